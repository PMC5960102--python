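"""Pairwise coding divergence (Nei-Gojobori dN/dS) and variant accounting.

The Nei-Gojobori (1986) method counts, for every codon, the fraction of
possible single-nucleotide changes that are synonymous ("synonymous
sites") and classifies observed differences between two aligned coding
sequences as synonymous or nonsynonymous, averaging over all mutational
pathways when a codon pair differs at more than one position.  The raw
proportions pS and pN are corrected for multiple hits with the
Jukes-Cantor formula d = -3/4 ln(1 - 4p/3), giving dS and dN; their ratio
dN/dS is below 1 under purifying selection and above 1 under positive
selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations, product

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"
_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)


def translate_codon(codon: str) -> str | None:
    """Amino acid for a codon; None for a stop codon."""
    return _CODON_TABLE.get(codon)


def _synonymous_site_fraction(codon: str) -> float:
    """Synonymous sites of one codon (0..3), NG86 convention.

    Per position, the fraction of the three possible changes that preserve
    the amino acid; changes creating a stop codon are treated as
    nonsynonymous.
    """
    aa = _CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt not in _STOPS and _CODON_TABLE[alt] == aa:
                syn += 1
        s += syn / 3.0
    return s


_SYN_SITES = {c: _synonymous_site_fraction(c) for c in _CODON_TABLE}


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous difference counts between two codons.

    Averages over every order of the single-nucleotide steps between the
    codons; pathways passing through a stop codon are excluded.  If every
    pathway is blocked by stops, all orders are used regardless (rare and
    degenerate, but keeps the count defined).
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    blocked = []
    for order in permutations(diff):
        cur = c1
        sd = nd = 0.0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                ok = False
            step_syn = (
                nxt not in _STOPS
                and cur not in _STOPS
                and _CODON_TABLE.get(cur) == _CODON_TABLE.get(nxt)
            )
            if step_syn:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (results if ok else blocked).append((sd, nd))
    use = results or blocked
    sd = sum(r[0] for r in use) / len(use)
    nd = sum(r[1] for r in use) / len(use)
    return sd, nd


_PAIR_COUNTS: dict = {}


def _pair_counts_cached(c1: str, c2: str) -> tuple[float, float]:
    key = (c1, c2)
    if key not in _PAIR_COUNTS:
        _PAIR_COUNTS[key] = _pathway_counts(c1, c2)
    return _PAIR_COUNTS[key]


@dataclass(frozen=True)
class DivergenceStats:
    """Nei-Gojobori site and difference counts for one coding pair."""

    gene_id: str
    n_codons: int
    n_skipped: int  # codons with ambiguity/stop, excluded from counting
    N: float
    S: float
    Nd: float
    Sd: float
    pN: float
    pS: float
    dN: float | None  # None when the Jukes-Cantor correction is undefined
    dS: float | None

    @property
    def ratio(self) -> float | None:
        """dN/dS; None when undefined or dS == 0."""
        if self.dN is None or self.dS is None or self.dS == 0:
            return None
        return self.dN / self.dS


def jukes_cantor(p: float) -> float | None:
    """Multiple-hit correction d = -3/4 ln(1 - 4p/3); undefined for p >= 3/4."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _clean_codons(seq1: str, seq2: str):
    """Yield comparable codon pairs; skip (and count) ambiguous/stop/gap codons."""
    if len(seq1) != len(seq2):
        raise ValueError("sequences must be aligned to equal length")
    usable, skipped = [], 0
    n = len(seq1) - len(seq1) % 3
    for i in range(0, n, 3):
        c1 = seq1[i : i + 3].upper()
        c2 = seq2[i : i + 3].upper()
        if (
            set(c1) | set(c2) <= set(BASES)
            and c1 not in _STOPS
            and c2 not in _STOPS
        ):
            usable.append((c1, c2))
        else:
            skipped += 1
    return usable, skipped


def nei_gojobori(seq1: str, seq2: str, gene_id: str = "") -> DivergenceStats:
    """Nei-Gojobori divergence statistics for one aligned coding pair.

    Site counts are averaged over the two sequences; observed differences
    are pathway-averaged per codon.  ``dN``/``dS`` are Jukes-Cantor
    corrected and flagged undefined (None) when the proportion reaches
    3/4.
    """
    usable, skipped = _clean_codons(seq1, seq2)
    if not usable:
        raise ValueError("no comparable codons")
    S1 = sum(_SYN_SITES[c1] for c1, _ in usable)
    S2 = sum(_SYN_SITES[c2] for _, c2 in usable)
    S = (S1 + S2) / 2.0
    N = 3.0 * len(usable) - S
    Sd = Nd = 0.0
    for c1, c2 in usable:
        sd, nd = _pair_counts_cached(c1, c2)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    return DivergenceStats(
        gene_id=gene_id,
        n_codons=len(usable),
        n_skipped=skipped,
        N=N,
        S=S,
        Nd=Nd,
        Sd=Sd,
        pN=pN,
        pS=pS,
        dN=jukes_cantor(pN),
        dS=jukes_cantor(pS),
    )


@dataclass(frozen=True)
class DivergenceSummary:
    mean_dS: float
    se_dS: float
    mean_dN: float
    se_dN: float
    n_genes: int
    n_undefined: int
    positive_selection_genes: tuple  # gene ids with dN/dS > 1


def aggregate_divergence(stats_list) -> DivergenceSummary:
    """Genome-level means and standard errors of dS and dN over genes.

    Pairs whose corrected estimate is undefined (saturated) are excluded
    and counted; genes with dN/dS > 1 are listed as candidates for
    positive selection.
    """
    stats_list = list(stats_list)
    defined = [s for s in stats_list if s.dS is not None and s.dN is not None]
    if not defined:
        raise ValueError("no defined divergence estimates")
    ds = np.array([s.dS for s in defined])
    dn = np.array([s.dN for s in defined])
    n = len(defined)
    se = lambda v: float(v.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    positive = tuple(
        s.gene_id for s in defined if s.ratio is not None and s.ratio > 1
    )
    return DivergenceSummary(
        float(ds.mean()), se(ds), float(dn.mean()), se(dn),
        n, len(stats_list) - n, positive,
    )


# --- variant classification -------------------------------------------------

SNP = "SNP"
INDEL = "indel"

REGION_CODING = "coding"
REGION_UTR = "UTR"
REGION_INTRON = "intron"
REGION_INTERGENIC = "intergenic"
REGION_OTHER_GENIC = "other-genic"

EFFECT_SILENT = "silent"
EFFECT_MISSENSE = "missense"
EFFECT_NONSENSE = "nonsense"
EFFECT_FRAMESHIFT = "frameshift"
EFFECT_INFRAME = "in-frame indel"
EFFECT_NONE = "none"


@dataclass(frozen=True)
class VariantRecord:
    seqid: str
    pos: int  # 1-based
    ref: str
    alt: str
    var_class: str
    region: str
    effect: str
    gene_id: str = ""


def _spliced_cds_coords(model) -> list:
    """Genomic positions of the spliced CDS in coding (5'->3') order."""
    segments = model.cds if model.cds else [(s, e, "0") for s, e in model.exons]
    positions = [p for s, e, *_ in segments for p in range(s, e + 1)]
    return positions[::-1] if model.strand == "-" else positions


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def classify_variant(
    seqid: str,
    pos: int,
    ref: str,
    alt: str,
    models,
    reference: dict,
) -> VariantRecord:
    """Region and coding-effect classification of one variant.

    Region precedence when annotations overlap: coding > UTR > intron >
    intergenic; a position inside any mRNA's CDS is coding.  A SNP in a CDS
    has its codon recomputed from the reference and classified as silent,
    missense or nonsense; a CDS indel is a frameshift unless its length is
    a multiple of 3.  The stated reference allele must match the reference
    sequence at the site.
    """
    if seqid not in reference:
        raise ValueError(f"unknown seqid {seqid!r}")
    contig = reference[seqid]
    if not 1 <= pos <= len(contig):
        raise ValueError(f"position {pos} outside {seqid}")
    var_class = SNP if len(ref) == 1 and len(alt) == 1 else INDEL
    observed = contig[pos - 1 : pos - 1 + len(ref)]
    if observed.upper() != ref.upper():
        raise ValueError(
            f"{seqid}:{pos} reference allele mismatch "
            f"(stated {ref!r}, sequence has {observed!r})"
        )
    best = (5, REGION_INTERGENIC, EFFECT_NONE, "")
    rank = {REGION_CODING: 0, REGION_UTR: 1, REGION_INTRON: 2, REGION_OTHER_GENIC: 3}
    for model in models:
        if model.seqid != seqid or not (model.start <= pos <= model.end):
            continue
        segments = model.cds if model.cds else [(s, e, "0") for s, e in model.exons]
        in_cds = any(s <= pos <= e for s, e, *_ in segments)
        in_utr = any(s <= pos <= e for s, e, *_ in model.utrs)
        in_intron = any(s <= pos <= e for s, e in model.introns)
        if in_cds:
            region = REGION_CODING
            effect = _coding_effect(model, contig, pos, ref, alt, var_class)
        elif in_utr:
            region, effect = REGION_UTR, EFFECT_NONE
        elif in_intron:
            region, effect = REGION_INTRON, EFFECT_NONE
        else:
            region, effect = REGION_OTHER_GENIC, EFFECT_NONE
        cand = (rank[region], region, effect, model.gene_id)
        if cand[0] < best[0]:
            best = cand
    return VariantRecord(
        seqid, pos, ref.upper(), alt.upper(), var_class, best[1], best[2], best[3]
    )


def _coding_effect(model, contig, pos, ref, alt, var_class) -> str:
    if var_class == INDEL:
        delta = abs(len(ref) - len(alt))
        return EFFECT_FRAMESHIFT if delta % 3 else EFFECT_INFRAME
    coords = _spliced_cds_coords(model)
    try:
        cds_index = coords.index(pos)
    except ValueError:
        return EFFECT_NONE
    codon_start = cds_index - cds_index % 3
    codon_coords = coords[codon_start : codon_start + 3]
    if len(codon_coords) < 3:
        return EFFECT_NONE  # trailing partial codon
    base = alt.upper()
    if model.strand == "-":
        base = base.translate(_COMPLEMENT)
    ref_codon = "".join(
        contig[p - 1].upper() if model.strand == "+" else
        contig[p - 1].upper().translate(_COMPLEMENT)
        for p in codon_coords
    )
    alt_codon = "".join(
        base if p == pos else c for p, c in zip(codon_coords, ref_codon)
    )
    if alt_codon in _STOPS:
        return EFFECT_NONSENSE
    if ref_codon in _STOPS:
        return EFFECT_MISSENSE  # stop-loss; lump with amino-acid change
    return (
        EFFECT_SILENT
        if _CODON_TABLE[ref_codon] == _CODON_TABLE[alt_codon]
        else EFFECT_MISSENSE
    )


def classify_variants(variants: pd.DataFrame, models, reference: dict) -> pd.DataFrame:
    """Vector version over a (seqid, pos, ref, alt) variant table."""
    recs = [
        classify_variant(r.seqid, int(r.pos), r.ref, r.alt, models, reference)
        for r in variants.itertuples(index=False)
    ]
    return pd.DataFrame(
        [
            (v.seqid, v.pos, v.ref, v.alt, v.var_class, v.region, v.effect, v.gene_id)
            for v in recs
        ],
        columns=["seqid", "pos", "ref", "alt", "class", "region", "effect", "gene_id"],
    )


def missense_silent_ratio(annotated: pd.DataFrame) -> float:
    """count(missense) / count(silent) over annotated variants."""
    silent = int((annotated.effect == EFFECT_SILENT).sum())
    missense = int((annotated.effect == EFFECT_MISSENSE).sum())
    if silent == 0:
        raise ValueError("no silent variants: ratio undefined")
    return missense / silent


def top_divergence_genes(
    missense_counts: dict, protein_lengths: dict, fraction: float = 0.05
):
    """Genes in the top ``fraction`` of missense changes per amino-acid site.

    Rate = missense count / protein length.  The top ceil(fraction * n)
    genes are selected; ties at the cutoff rate are all included (the
    selection is then larger than the nominal count and flagged).
    Returns ``(selected_ids, tied_at_cutoff)``.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if set(missense_counts) - set(protein_lengths):
        raise ValueError("missing protein lengths for some genes")
    rates = {}
    for gid, cnt in missense_counts.items():
        length = protein_lengths[gid]
        if length <= 0:
            raise ValueError(f"{gid}: non-positive protein length")
        rates[gid] = cnt / length
    n = len(rates)
    k = math.ceil(fraction * n)
    ordered = sorted(rates, key=lambda g: (-rates[g], g))
    cutoff = rates[ordered[k - 1]]
    selected = frozenset(g for g in rates if rates[g] >= cutoff)
    tied = len(selected) > k
    return selected, tied
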