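"""GFF3-backed gene models: exon/intron accounting and spliced CDS extraction.

Coordinates are GFF3 style throughout: 1-based, inclusive on both ends.
One model represents one mRNA; for genes with several isoforms the
longest-CDS isoform is taken as the representative, so per-gene summaries
(total exon length, total intron length) have a single value per gene.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd


@dataclass
class GeneModel:
    """One gene model (representative mRNA) in genomic coordinates."""

    gene_id: str
    transcript_id: str
    seqid: str
    strand: str
    exons: list  # [(start, end)] 1-based inclusive, sorted by start
    cds: list = field(default_factory=list)  # [(start, end, phase)]
    utrs: list = field(default_factory=list)  # [(start, end, kind)]

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"{self.gene_id}: inverted exon {s}-{e}")
        for (s1, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"{self.gene_id}: overlapping exons {s1}-{e1} and {s2}-.."
                )

    @property
    def introns(self) -> list:
        """Gaps between consecutive exons, 1-based inclusive."""
        return [
            (e1 + 1, s2 - 1)
            for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def exons_transcript_order(self) -> list:
        return self.exons if self.strand == "+" else self.exons[::-1]

    def introns_transcript_order(self) -> list:
        ints = self.introns
        return ints if self.strand == "+" else ints[::-1]


def read_annotation(source, representative: str = "longest_cds") -> list[GeneModel]:
    """Read gene models from a GFF3 file path or literal GFF3 text.

    Expects ``gene``/``mRNA``/``exon``/``CDS`` (optionally UTR) features
    linked by ``Parent``.  A child whose parent is undeclared is an error;
    so are overlapping exons within one mRNA.  Per gene, the representative
    mRNA is the one with the longest total CDS ("longest_cds", default) or
    the first by id ("first").
    """
    data = source
    from_string = isinstance(source, str) and "\n" in source
    if not from_string:
        with open(source) as fh:
            data = fh.read()
    db = gffutils.create_db(
        data,
        dbfn=":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    known = {f.id for f in db.all_features()}
    for feat in db.all_features():
        for parent_id in feat.attributes.get("Parent", []):
            if parent_id not in known:
                raise ValueError(
                    f"feature {feat.id!r} references undeclared parent "
                    f"{parent_id!r}"
                )
    models = []
    for gene in db.features_of_type("gene"):
        candidates = []
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = [(f.start, f.end) for f in db.children(mrna, featuretype="exon")]
            cds = [
                (f.start, f.end, f.frame if f.frame != "." else "0")
                for f in db.children(mrna, featuretype="CDS")
            ]
            utrs = [
                (f.start, f.end, f.featuretype)
                for f in db.children(
                    mrna, featuretype=("five_prime_UTR", "three_prime_UTR")
                )
            ]
            if not exons:
                continue
            model = GeneModel(
                gene_id=gene.id,
                transcript_id=mrna.id,
                seqid=gene.seqid,
                strand=gene.strand,
                exons=exons,
                cds=sorted((s, e, ph) for s, e, ph in cds),
                utrs=sorted(utrs),
            )
            candidates.append(model)
        if not candidates:
            continue
        if representative == "longest_cds":
            candidates.sort(
                key=lambda m: (
                    -sum(e - s + 1 for s, e, _ in m.cds),
                    -sum(e - s + 1 for s, e in m.exons),
                    m.transcript_id,
                )
            )
        elif representative == "first":
            candidates.sort(key=lambda m: m.transcript_id)
        else:
            raise ValueError(f"unknown representative rule {representative!r}")
        models.append(candidates[0])
    return models


def write_annotation(models, path) -> None:
    """Write models back to GFF3 (gene/mRNA/exon/CDS/UTR, 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            base = f"{m.seqid}\thymevol\t"
            tail = f"\t.\t{m.strand}\t"
            fh.write(
                f"{base}gene\t{m.start}\t{m.end}{tail}.\tID={m.gene_id}\n"
            )
            fh.write(
                f"{base}mRNA\t{m.start}\t{m.end}{tail}.\t"
                f"ID={m.transcript_id};Parent={m.gene_id}\n"
            )
            for i, (s, e) in enumerate(m.exons, 1):
                fh.write(
                    f"{base}exon\t{s}\t{e}{tail}.\t"
                    f"ID={m.transcript_id}.exon{i};Parent={m.transcript_id}\n"
                )
            for i, (s, e, ph) in enumerate(m.cds, 1):
                fh.write(
                    f"{m.seqid}\thymevol\tCDS\t{s}\t{e}\t.\t{m.strand}\t{ph}\t"
                    f"ID={m.transcript_id}.cds;Parent={m.transcript_id}\n"
                )
            for s, e, kind in m.utrs:
                fh.write(
                    f"{base}{kind}\t{s}\t{e}{tail}.\t"
                    f"ID={m.transcript_id}.{kind};Parent={m.transcript_id}\n"
                )


def exon_intron_totals(model: GeneModel) -> tuple[int, int]:
    """Total exon bp and total intron bp of one gene model."""
    exon_bp = sum(e - s + 1 for s, e in model.exons)
    intron_bp = sum(e - s + 1 for s, e in model.introns)
    return exon_bp, intron_bp


@dataclass(frozen=True)
class LengthComparison:
    means: pd.Series
    f_statistic: float
    p: float
    tukey: pd.DataFrame  # pairwise honest-significant-difference table


def length_comparison(groups: dict) -> LengthComparison:
    """One-way ANOVA plus Tukey HSD across per-species length totals.

    ``groups`` maps species name to a sequence of per-gene totals (exon or
    intron bp).  Raw totals are compared by default; callers wanting a log
    scale transform their inputs first.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 species groups")
    for sp, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {sp!r} has fewer than 2 values")
    names = sorted(groups)
    arrays = [np.asarray(groups[sp], dtype=float) for sp in names]
    f_stat, p = stats.f_oneway(*arrays)
    values = np.concatenate(arrays)
    labels = np.concatenate([[sp] * len(a) for sp, a in zip(names, arrays)])
    tk = pairwise_tukeyhsd(values, labels)
    tukey = pd.DataFrame(
        tk.summary().data[1:], columns=tk.summary().data[0]
    )
    means = pd.Series({sp: float(a.mean()) for sp, a in zip(names, arrays)})
    return LengthComparison(means, float(f_stat), float(p), tukey)


def _load_genome(genome) -> dict:
    if isinstance(genome, dict):
        return genome
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(genome, "fasta")}


def extract_cds(genome, models) -> dict:
    """Spliced, strand-oriented CDS per model from a genome FASTA or dict.

    Minus-strand models are reverse-complemented into coding orientation.
    CDS segments outside the contig, or an unknown seqid, are errors.
    """
    contigs = _load_genome(genome)
    out = {}
    for m in models:
        if m.seqid not in contigs:
            raise ValueError(f"{m.gene_id}: unknown seqid {m.seqid!r}")
        contig = contigs[m.seqid]
        segments = m.cds if m.cds else [(s, e, "0") for s, e in m.exons]
        parts = []
        for s, e, _ in segments:
            if s < 1 or e > len(contig):
                raise ValueError(
                    f"{m.gene_id}: CDS {s}-{e} outside {m.seqid} "
                    f"(length {len(contig)})"
                )
            parts.append(contig[s - 1 : e])
        seq = "".join(parts)
        if m.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        out[m.gene_id] = seq
    return out


def write_fasta(records: dict, path, width: int = 80) -> None:
    """Write an id -> sequence mapping as wrapped FASTA."""
    with open(path, "w") as fh:
        for rid, seq in records.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
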