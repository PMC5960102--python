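"""Gene-body methylation: CpG depletion, bisulfite fractions, conservation.

Methylcytosine is mutagenic and occurs mostly in the CpG context, so genes
with a history of germline methylation are depleted of CpG dinucleotides:
their observed/expected CpG ratio falls below 1 while the GpC control is
unaffected.  Direct evidence comes from bisulfite sequencing: the
*fractional methylation* of a gene is the read-weighted fraction of
methylated calls over its covered CpG sites, and a gene is called
methylated when that fraction exceeds 0.01.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from hymevol.annotation import GeneModel

METHYLATED = "methylated"
UNMETHYLATED = "unmethylated"
NO_DATA = "no-data"

#: Gene-body fractional methylation above which a gene is called methylated.
METHYLATION_THRESHOLD = 0.01

SITE_COLUMNS = ("seqid", "pos", "strand", "context", "meth_reads", "total_reads")


@dataclass(frozen=True)
class DinucleotideOE:
    """Observed/expected ratio of one dinucleotide in one sequence."""

    n_dinucleotide: int
    n_first: int
    n_second: int
    length: int
    oe: float | None  # None when expectation is undefined (no X or no Y)

    @property
    def defined(self) -> bool:
        return self.oe is not None


def dinucleotide_oe(sequence: str, dinucleotide: str = "CG") -> DinucleotideOE:
    """Observed/expected ratio of an overlapping dinucleotide count.

    O/E = (N_XY * L) / (N_X * N_Y) with N_XY counted over overlapping
    windows.  Positions holding ``N`` are excluded from the base counts and
    from L, and windows containing an ``N`` are skipped.  A sequence with
    no X or no Y has an undefined expectation and is flagged rather than
    raised.
    """
    seq = sequence.upper()
    if len(seq) < 2:
        raise ValueError("sequence must have length >= 2")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid bases {sorted(bad)}")
    x, y = dinucleotide.upper()
    length = sum(1 for c in seq if c != "N")
    n_x = seq.count(x) if x != "N" else 0
    n_y = seq.count(y) if y != "N" else 0
    n_xy = sum(
        1
        for i in range(len(seq) - 1)
        if seq[i] == x and seq[i + 1] == y
    )
    if n_x == 0 or n_y == 0:
        return DinucleotideOE(n_xy, n_x, n_y, length, None)
    return DinucleotideOE(n_xy, n_x, n_y, length, n_xy * length / (n_x * n_y))


def cds_oe_table(cds: dict) -> pd.DataFrame:
    """CpG and GpC O/E per CDS (gene_id, cpg_oe, gpc_oe, length)."""
    rows = []
    for gid, seq in cds.items():
        cpg = dinucleotide_oe(seq, "CG")
        gpc = dinucleotide_oe(seq, "GC")
        rows.append((gid, cpg.oe, gpc.oe, cpg.length))
    return pd.DataFrame(rows, columns=["gene_id", "cpg_oe", "gpc_oe", "length"])


@dataclass(frozen=True)
class GeneMethylation:
    gene_id: str
    fraction: float | None
    n_sites: int
    status: str


def classify_methylated(fraction: float, threshold: float = METHYLATION_THRESHOLD) -> str:
    """Methylated iff fraction strictly exceeds the threshold (default 0.01)."""
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    return METHYLATED if fraction > threshold else UNMETHYLATED


def _sites_in_span(sites: pd.DataFrame, seqid: str, start: int, end: int) -> pd.DataFrame:
    return sites[
        (sites.seqid == seqid) & (sites.pos >= start) & (sites.pos <= end)
    ]


def gene_fractional_methylation(
    sites: pd.DataFrame,
    model: GeneModel,
    min_coverage: int = 1,
    min_sites: int = 3,
    threshold: float = METHYLATION_THRESHOLD,
    weighted: bool = True,
) -> GeneMethylation:
    """Read-weighted gene-body fractional methylation and status call.

    The gene body is the full transcribed span (exons plus introns).  Sites
    below ``min_coverage`` total reads are excluded; a gene with no covered
    site has no-data status, and one with fewer than ``min_sites`` covered
    sites is left uncalled the same way (too little evidence for a status).
    ``weighted=False`` switches to the unweighted mean of per-site
    fractions.
    """
    sub = _sites_in_span(sites, model.seqid, model.start, model.end)
    sub = sub[sub.total_reads >= max(min_coverage, 1)]
    n = len(sub)
    if n == 0:
        return GeneMethylation(model.gene_id, None, 0, NO_DATA)
    if weighted:
        fraction = float(sub.meth_reads.sum() / sub.total_reads.sum())
    else:
        fraction = float((sub.meth_reads / sub.total_reads).mean())
    if n < min_sites:
        return GeneMethylation(model.gene_id, fraction, n, NO_DATA)
    return GeneMethylation(
        model.gene_id, fraction, n, classify_methylated(fraction, threshold)
    )


def methylation_table(sites: pd.DataFrame, models, **kwargs) -> pd.DataFrame:
    """Per-gene fractional methylation table over a set of gene models."""
    recs = [gene_fractional_methylation(sites, m, **kwargs) for m in models]
    return pd.DataFrame(
        [(r.gene_id, r.fraction, r.n_sites, r.status) for r in recs],
        columns=["gene_id", "fraction", "n_sites", "status"],
    )


def positional_profile(
    models, sites: pd.DataFrame, statuses: dict, n_features: int = 4,
    min_coverage: int = 1,
) -> pd.DataFrame:
    """Mean fractional methylation in the first/last exons and introns.

    Feature slots follow transcript orientation: the first ``n_features``
    exons, last ``n_features`` exons, and likewise for introns.  Each gene
    contributes a read-weighted fraction to every slot it actually has (a
    single-exon gene only to first-exon-1 and last-exon-1); slot means are
    taken over contributing genes, separately for the methylated and
    unmethylated sets given in ``statuses`` (gene_id -> status).

    Returns a tidy DataFrame (status, feature, position, which_end,
    mean_fraction, n_genes).
    """
    acc = {}
    for model in models:
        status = statuses.get(model.gene_id)
        if status not in (METHYLATED, UNMETHYLATED):
            continue
        for feature, intervals in (
            ("exon", model.exons_transcript_order()),
            ("intron", model.introns_transcript_order()),
        ):
            k = len(intervals)
            for which_end, ordered in (("first", intervals), ("last", intervals[::-1])):
                for idx in range(min(n_features, k)):
                    s, e = ordered[idx]
                    sub = _sites_in_span(sites, model.seqid, s, e)
                    sub = sub[sub.total_reads >= max(min_coverage, 1)]
                    if not len(sub):
                        continue
                    frac = float(sub.meth_reads.sum() / sub.total_reads.sum())
                    acc.setdefault(
                        (status, feature, which_end, idx + 1), []
                    ).append(frac)
    rows = [
        (status, feature, which_end, pos, float(np.mean(v)), len(v))
        for (status, feature, which_end, pos), v in sorted(acc.items())
    ]
    return pd.DataFrame(
        rows,
        columns=["status", "feature", "which_end", "position", "mean_fraction", "n_genes"],
    )


CONSERVED_METHYLATED = "conserved_methylated"
CONSERVED_UNMETHYLATED = "conserved_unmethylated"
FOCAL_GAIN = "focal_gain"
FOCAL_LOSS = "focal_loss"
OTHER = "other"
EXCLUDED = "excluded"

CONSERVATION_LABELS = (
    CONSERVED_METHYLATED,
    FOCAL_GAIN,
    FOCAL_LOSS,
    CONSERVED_UNMETHYLATED,
    OTHER,
)


def conservation_label(focal_status: str, other_statuses) -> str:
    """Label one ortholog's cross-species methylation-status tuple."""
    others = list(other_statuses)
    if focal_status == NO_DATA or NO_DATA in others:
        return EXCLUDED
    all_m = all(s == METHYLATED for s in others)
    all_u = all(s == UNMETHYLATED for s in others)
    if focal_status == METHYLATED and all_m:
        return CONSERVED_METHYLATED
    if focal_status == METHYLATED and all_u:
        return FOCAL_GAIN
    if focal_status == UNMETHYLATED and all_m:
        return FOCAL_LOSS
    if focal_status == UNMETHYLATED and all_u:
        return CONSERVED_UNMETHYLATED
    return OTHER  # gains/losses specific to a non-focal lineage


def conservation_table(statuses: pd.DataFrame, focal_species: str):
    """Cross-species conservation accounting over single-copy orthologs.

    ``statuses`` is an ortholog x species table of status strings.  Returns
    ``(records, counts)`` where ``records`` adds a ``label`` column and
    ``counts`` tallies each label (including orthologs excluded for
    missing data).  Labels partition the orthologs: conserved methylated /
    focal-specific gain / focal-specific loss / conserved unmethylated /
    other (changes specific to a non-focal lineage).
    """
    if focal_species not in statuses.columns:
        raise ValueError(f"focal species {focal_species!r} not in table")
    if statuses.shape[1] < 3:
        raise ValueError("need >= 3 species for conservation labels")
    others = [c for c in statuses.columns if c != focal_species]
    labels = statuses.apply(
        lambda row: conservation_label(row[focal_species], row[others]), axis=1
    )
    records = statuses.assign(label=labels)
    counts = labels.value_counts().reindex(
        list(CONSERVATION_LABELS) + [EXCLUDED], fill_value=0
    )
    return records, counts


def ortholog_methylation_correlation(
    fractions_a, fractions_b, floor: float = 1e-4
) -> tuple[float, float]:
    """Pearson correlation of log10(fraction + floor) over paired orthologs.

    The floor keeps fully unmethylated genes finite on the log scale; the
    default sits two orders of magnitude below the 0.01 status threshold.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    a = np.asarray(fractions_a, dtype=float)
    b = np.asarray(fractions_b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need >= 3 paired fractions")
    r, p = stats.pearsonr(np.log10(a + floor), np.log10(b + floor))
    return float(r), float(p)


def read_site_table(path) -> pd.DataFrame:
    """Read a per-site bisulfite call TSV with the standard header."""
    df = pd.read_csv(path, sep="\t")
    missing = set(SITE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"site table missing columns {sorted(missing)}")
    if ((df.meth_reads < 0) | (df.meth_reads > df.total_reads)).any():
        raise ValueError("meth_reads must satisfy 0 <= meth <= total")
    return df
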