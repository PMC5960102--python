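"""Synthetic inputs with known ground truth for every analysis stage.

Each generator emulates the statistical structure its downstream analysis
assumes, at the study conditions of the comparative analyses this package
implements — an eight-taxon species phylogeny with a four-wasp focal
clade, per-ortholog baseline rates with lineage-specific multipliers,
triple protein alignments with asymmetric lineage substitution counts, a
bimodally CpG-depleted CDS population with binomial bisulfite read counts,
cluster tables with known category composition, and coding pairs with
chosen dN and dS.  Ground truth is recorded alongside every artifact so
parameter recovery can be tested end to end.

Determinism: every generator draws from its own RNG stream, seeded from
the configuration seed combined with the generator's name, so outputs are
byte-identical under a fixed seed and adding a generator never perturbs
the others.
"""

from __future__ import annotations

import math
import os
import zlib
from dataclasses import dataclass, field
from itertools import product

import dendropy
import numpy as np
import pandas as pd

from hymevol.annotation import GeneModel, write_annotation, write_fasta
from hymevol.clusters import ClusterTable
from hymevol.phylo import OrthologTreeSet, SpeciesPhylogeny, default_phylogeny
from hymevol.relative_rate import AMINO_ACIDS, TripleAlignment

_AA = np.array(list(AMINO_ACIDS))
_DNA = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Shared knobs of the synthetic-data generators.

    Defaults are the study conditions the analyses assume: 1311 core
    single-copy orthologs is the scale of the place-ranking analyses (use
    ``n_orthologs`` to scale down), 37.4% of genes methylated with a
    strong/near-zero split of true fractional methylation, 20x mean
    bisulfite coverage, and a genome-wide synonymous divergence of 0.013
    for the coding pairs.
    """

    seed: int = 0
    n_orthologs: int = 400
    species_tree: SpeciesPhylogeny = field(default_factory=default_phylogeny)
    baseline_rate_shape: float | None = 2.0  # gamma shape; None = no variance
    branch_noise_shape: float | None = 5.0  # per-branch gamma noise; None = off
    lineage_multipliers: dict = field(default_factory=dict)
    alignment_length: int = 500
    # per-site substitution rates on the (A-only, B-only, O-only, shared) branches
    triple_rates: tuple = (0.03, 0.03, 0.06, 0.02)
    n_genes: int = 300
    meth_class_proportions: tuple = (0.374, 0.626)  # (methylated, unmethylated)
    meth_class_fractions: tuple = (0.9, 0.001)  # true fractional methylation
    depletion_strength: float = 0.6  # CpG depletion of the methylated class
    coverage_mean: float = 20.0
    conversion_error: float = 0.0  # bisulfite non-conversion noise
    five_prime_bias: float = 0.0  # per-feature exponential decay of methylation
    n_pairs: int = 200
    codons_per_pair: int = 500
    ds_target: float = 0.013
    dn_target: float = 0.004

    def __post_init__(self):
        if abs(sum(self.meth_class_proportions) - 1.0) > 1e-9:
            raise ValueError("meth_class_proportions must sum to 1")
        if any(p < 0 for p in self.meth_class_proportions):
            raise ValueError("proportions must be non-negative")
        taxa = set(self.species_tree.taxa)
        for branch, mult in self.lineage_multipliers.items():
            if mult <= 0:
                raise ValueError(
                    f"non-positive multiplier {mult} for branch {branch!r}"
                )
            if branch not in taxa:
                raise ValueError(f"multiplier names unknown branch {branch!r}")
        for name in ("baseline_rate_shape", "branch_noise_shape"):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise ValueError(f"{name} must be positive (or None)")
        if self.alignment_length < 1:
            raise ValueError("alignment_length must be >= 1")
        if any(r < 0 for r in self.triple_rates):
            raise ValueError("triple_rates must be non-negative")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")
        if not 0 <= self.depletion_strength <= 1:
            raise ValueError("depletion_strength must be in [0, 1]")
        if not 0 <= self.conversion_error < 0.5:
            raise ValueError("conversion_error must be in [0, 0.5)")
        for name in ("ds_target", "dn_target"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value >= 0):
                raise ValueError(f"{name} must be finite and >= 0")
        # targets must stay invertible through the Jukes-Cantor correction
        for name in ("ds_target", "dn_target"):
            p = _jc_forward(getattr(self, name))
            if p >= 0.75:
                raise ValueError(f"{name} implies a proportion >= 3/4")


def _jc_forward(d: float) -> float:
    """Expected raw difference proportion for a Jukes-Cantor distance d."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def _rng(config: SimulationConfig, generator: str) -> np.random.Generator:
    """One independent, reproducible stream per generator."""
    return np.random.default_rng(
        [config.seed & 0x7FFFFFFF, zlib.crc32(generator.encode())]
    )


# --- gene trees -------------------------------------------------------------

def expected_anchor_distances(config: SimulationConfig) -> pd.DataFrame:
    """Analytic expectations of the anchored distances under the tree model.

    Branch length = base length x per-ortholog gamma rate (mean 1) x
    lineage multiplier (applied to the species' terminal branch), so the
    expected species-to-clade-root distance is the multiplier-scaled path
    sum on the species tree.
    """
    phylo = config.species_tree
    rows = []
    tree = phylo.tree
    clade_node = phylo.clade_root()
    order_node = phylo.order_root()

    def scaled_path(leaf, anchor):
        total, cur = 0.0, leaf
        while cur is not anchor:
            length = cur.edge.length or 0.0
            if cur.is_leaf():
                length *= config.lineage_multipliers.get(cur.taxon.label, 1.0)
            total += length
            cur = cur.parent_node
        return total

    # internal path: clade root to order root never includes terminal edges
    cur, base = clade_node, 0.0
    while cur is not order_node:
        base += cur.edge.length or 0.0
        cur = cur.parent_node
    for leaf in tree.leaf_node_iter():
        sp = leaf.taxon.label
        if sp not in phylo.order_members:
            continue
        clade_d = (
            scaled_path(leaf, clade_node) if sp in phylo.clade_members else math.nan
        )
        order_d = scaled_path(leaf, order_node)
        rows.append((sp, clade_d, order_d, base))
    return pd.DataFrame(
        rows, columns=["species", "clade_dist", "order_dist", "base_dist"]
    )


def simulate_gene_trees(config: SimulationConfig):
    """Per-ortholog gene trees under the multiplicative branch model.

    Every tree keeps the species topology; each branch length is the
    species-tree base length times a per-ortholog gamma-distributed rate
    (unit mean, shape ``baseline_rate_shape``) times an iid per-branch
    gamma noise factor (unit mean, shape ``branch_noise_shape``; ``None``
    turns the noise off) times the lineage multiplier of the terminal
    branch it subtends (1 for internal branches and unlisted species).
    The branch noise is what lets different orthologs rank the species
    differently; without it every gene tree would place the species
    identically.

    Returns ``(tree_set, truth)`` where truth holds the per-(ortholog,
    species) anchored distances realised in each emitted tree, plus the
    per-ortholog rate draw.
    """
    phylo = config.species_tree
    rng = _rng(config, "gene_trees")
    if config.baseline_rate_shape is None:
        rates = np.ones(config.n_orthologs)
    else:
        shape = config.baseline_rate_shape
        rates = rng.gamma(shape, 1.0 / shape, size=config.n_orthologs)

    # fixed template structures: preorder node list and, per species, the
    # branch-index paths to the two anchors (plus the clade->order stem)
    template = phylo.tree
    nodes = list(template.preorder_node_iter())
    index_of = {id(nd): i for i, nd in enumerate(nodes)}
    clade_node = phylo.clade_root()
    order_node = phylo.order_root()

    def branch_path(node, ancestor):
        path, cur = [], node
        while cur is not ancestor:
            path.append(index_of[id(cur)])
            cur = cur.parent_node
        return path

    base_path = branch_path(clade_node, order_node)
    species_paths = {}
    for leaf in template.leaf_node_iter():
        sp = leaf.taxon.label
        if sp not in phylo.order_members:
            continue
        to_order = branch_path(leaf, order_node)
        to_clade = branch_path(leaf, clade_node) if sp in phylo.clade_members else None
        species_paths[sp] = (to_clade, to_order)
    base_lengths = np.array([nd.edge.length or 0.0 for nd in nodes])
    mults = np.array(
        [
            config.lineage_multipliers.get(nd.taxon.label, 1.0)
            if nd.is_leaf() and nd.taxon is not None
            else 1.0
            for nd in nodes
        ]
    )

    trees, rows = {}, []
    width = max(4, len(str(config.n_orthologs)))
    for i, rate in enumerate(rates):
        oid = f"OG{i:0{width}d}"
        if config.branch_noise_shape is None:
            noise = np.ones(len(nodes))
        else:
            bs = config.branch_noise_shape
            noise = rng.gamma(bs, 1.0 / bs, size=len(nodes))
        scaled = base_lengths * rate * noise * mults
        tree = dendropy.Tree(template)  # deep clone, shared taxon namespace
        for j, nd in enumerate(tree.preorder_node_iter()):
            if nd.edge.length is not None:
                nd.edge.length = float(scaled[j])
        trees[oid] = tree
        base_d = float(scaled[base_path].sum())
        for sp, (to_clade, to_order) in species_paths.items():
            clade_d = float(scaled[to_clade].sum()) if to_clade is not None else math.nan
            order_d = float(scaled[to_order].sum())
            rows.append((oid, sp, clade_d, order_d, base_d, rate))
    truth = pd.DataFrame(
        rows,
        columns=["ortholog_id", "species", "clade_dist", "order_dist", "base_dist", "rate"],
    )
    return OrthologTreeSet(trees=trees), truth


# --- triple alignments ------------------------------------------------------

def simulate_triple_alignments(config: SimulationConfig, rates: tuple | None = None):
    """Triple (A, B, O) protein alignments with per-branch substitution counts.

    ``rates`` are per-site substitution probabilities on the A-only,
    B-only, O-only and shared-ingroup branches (defaults from the config).
    Substituted site counts are binomial in the alignment length, so the
    expected unique-substitution count on each branch equals length x
    rate.  Returns ``(alignments, truth)`` with the planted per-branch
    counts.
    """
    rate_a, rate_b, rate_o, rate_shared = rates or config.triple_rates
    for r in (rate_a, rate_b, rate_o, rate_shared):
        if r < 0:
            raise ValueError("rates must be non-negative")
    L = config.alignment_length
    rng = _rng(config, "triple_alignments")
    alignments, rows = [], []
    width = max(4, len(str(config.n_orthologs)))
    for i in range(config.n_orthologs):
        oid = f"OG{i:0{width}d}"
        anc = rng.choice(_AA, size=L)
        internal = anc.copy()
        n_shared = _substitute(rng, internal, rate_shared)
        a = internal.copy()
        b = internal.copy()
        o = anc.copy()
        n_a = _substitute(rng, a, rate_a)
        n_b = _substitute(rng, b, rate_b)
        n_o = _substitute(rng, o, rate_o)
        alignments.append(
            TripleAlignment(oid, "".join(a), "".join(b), "".join(o))
        )
        rows.append((oid, n_a, n_b, n_o, n_shared))
    truth = pd.DataFrame(
        rows, columns=["ortholog_id", "n_sub_a", "n_sub_b", "n_sub_o", "n_sub_shared"]
    )
    return alignments, truth


def _substitute(rng, seq: np.ndarray, rate: float) -> int:
    """Substitute Binomial(L, rate) sites in place; each to a new residue."""
    n = rng.binomial(len(seq), min(rate, 1.0))
    if n == 0:
        return 0
    sites = rng.choice(len(seq), size=n, replace=False)
    for s in sites:
        choices = _AA[_AA != seq[s]]
        seq[s] = rng.choice(choices)
    return int(n)


# --- methylome --------------------------------------------------------------

@dataclass
class SyntheticMethylome:
    """Genome, gene models, CDS, bisulfite site table and ground truth."""

    genome: dict  # contig -> sequence
    models: list  # GeneModel per gene
    cds: dict  # gene_id -> spliced CDS
    sites: pd.DataFrame  # seqid pos strand context meth_reads total_reads
    truth: pd.DataFrame  # gene_id meth_class true_fraction

    def write(self, outdir) -> None:
        os.makedirs(outdir, exist_ok=True)
        write_fasta(self.genome, os.path.join(outdir, "genome.fasta"))
        write_fasta(self.cds, os.path.join(outdir, "cds.fasta"))
        write_annotation(self.models, os.path.join(outdir, "annotation.gff3"))
        self.sites.to_csv(os.path.join(outdir, "sites.tsv"), sep="\t", index=False)
        self.truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)


def _depleted_sequence(rng, length: int, depletion: float) -> np.ndarray:
    """Uniform-composition sequence with CpG dinucleotides thinned.

    First-order chain: after a C, the probability of G is scaled by
    (1 - depletion) and the remainder redistributed, so the CpG
    observed/expected ratio comes out near (1 - depletion) while the GpC
    control stays near 1.
    """
    seq = rng.choice(_DNA, size=length)
    if depletion <= 0:
        return seq
    # rewrite G's that follow a C with probability = depletion
    prev_c = np.concatenate([[False], seq[:-1] == "C"])
    hit = prev_c & (seq == "G") & (rng.random(length) < depletion)
    if hit.any():
        repl = rng.choice(np.array(list("ACT")), size=int(hit.sum()))
        seq[hit] = repl
    return seq


def simulate_methylome(config: SimulationConfig) -> SyntheticMethylome:
    """Bimodally CpG-depleted gene set with binomial bisulfite calls.

    Genes fall into a methylated class (true fractional methylation drawn
    around the first entry of ``meth_class_fractions``, CpG-depleted CDS)
    and an unmethylated class (near-zero methylation, undepleted).  Each
    CpG site in a gene body receives Poisson(coverage_mean) total reads
    and binomial methylated reads at the gene's true per-site fraction;
    an optional five-prime bias decays the per-site fraction over
    transcript-ordered features.
    """
    rng = _rng(config, "methylome")
    p_meth = config.meth_class_proportions[0]
    f_meth, f_unmeth = config.meth_class_fractions
    genes_per_contig = 25
    genome, models, cds, truth_rows, site_rows = {}, [], {}, [], []
    contig_parts, contig_id, offset = [], 0, 0

    def flush_contig():
        nonlocal contig_parts, contig_id, offset
        if contig_parts:
            genome[f"contig{contig_id:03d}"] = "".join(contig_parts)
            contig_id += 1
            contig_parts, offset = [], 0

    for i in range(config.n_genes):
        gid = f"gene{i:05d}"
        seqid = f"contig{contig_id:03d}"
        is_meth = rng.random() < p_meth
        if is_meth:
            conc = 50.0
            tf = float(rng.beta(f_meth * conc, (1 - f_meth) * conc))
            depletion = config.depletion_strength
        else:
            tf = f_unmeth
            depletion = 0.0
        n_exons = int(rng.integers(1, 7))
        exon_lens = (rng.integers(40, 160, size=n_exons) * 3).tolist()
        intron_lens = rng.integers(60, 200, size=max(n_exons - 1, 0)).tolist()
        strand = "+" if rng.random() < 0.5 else "-"
        spacer = int(rng.integers(100, 300))
        contig_parts.append("".join(rng.choice(_DNA, size=spacer)))
        offset += spacer
        start = offset + 1
        exons, body_parts = [], []
        pos = start
        for k in range(n_exons):
            exon_seq = _depleted_sequence(rng, exon_lens[k], depletion)
            exons.append((pos, pos + exon_lens[k] - 1))
            body_parts.append("".join(exon_seq))
            pos += exon_lens[k]
            if k < n_exons - 1:
                intron_seq = _depleted_sequence(rng, intron_lens[k], depletion)
                body_parts.append("".join(intron_seq))
                pos += intron_lens[k]
        body = "".join(body_parts)
        contig_parts.append(body)
        offset += len(body)
        model = GeneModel(
            gene_id=gid,
            transcript_id=f"{gid}.t1",
            seqid=seqid,
            strand=strand,
            exons=exons,
            cds=[(s, e, "0") for s, e in exons],
        )
        models.append(model)
        spliced = "".join(
            body[s - start : e - start + 1] for s, e in exons
        )
        if strand == "-":
            spliced = spliced[::-1].translate(str.maketrans("ACGT", "TGCA"))
        cds[gid] = spliced
        truth_rows.append((gid, "methylated" if is_meth else "unmethylated", tf))
        site_rows.extend(
            _bisulfite_sites(rng, config, model, body, start, tf)
        )
        if (i + 1) % genes_per_contig == 0:
            flush_contig()
    flush_contig()
    sites = pd.DataFrame(
        site_rows,
        columns=["seqid", "pos", "strand", "context", "meth_reads", "total_reads"],
    )
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "meth_class", "true_fraction"])
    return SyntheticMethylome(genome, models, cds, sites, truth)


def _bisulfite_sites(rng, config, model, body, start, true_fraction):
    """Binomial read counts at every CpG of one gene body (+ strand C position)."""
    rows = []
    features = [("exon", iv) for iv in model.exons_transcript_order()]
    features += [("intron", iv) for iv in model.introns_transcript_order()]
    feature_index = {}
    exon_i = intron_i = 0
    for kind, iv in features:
        if kind == "exon":
            feature_index[iv] = exon_i
            exon_i += 1
        else:
            feature_index[iv] = intron_i
            intron_i += 1
    for k in range(len(body) - 1):
        if body[k] != "C" or body[k + 1] != "G":
            continue
        pos = start + k
        f_site = true_fraction
        if config.five_prime_bias > 0:
            for kind, (s, e) in features:
                if s <= pos <= e:
                    f_site *= math.exp(-config.five_prime_bias * feature_index[(s, e)])
                    break
        eps = config.conversion_error
        f_obs = f_site * (1 - eps) + (1 - f_site) * eps
        total = int(rng.poisson(config.coverage_mean))
        if total == 0:
            continue
        meth = int(rng.binomial(total, min(f_obs, 1.0)))
        rows.append((model.seqid, pos, "+", "CpG", meth, total))
    return rows


# --- cluster tables ---------------------------------------------------------

@dataclass(frozen=True)
class CategoryComposition:
    """Requested family composition for the synthetic cluster table.

    Scalar counts apply per species where relevant; ``n_missing`` plants,
    for each species, that many families present in every other species
    (sole-absentee "missing" families, a subset of the dispensable
    category).
    """

    n_single_copy_core: int = 10
    n_variable_copy_core: int = 5
    n_dispensable: int = 8
    n_species_specific: int = 2  # families per species, 2-4 genes each
    n_singletons: int = 3  # unclustered genes per species
    n_missing: int = 1  # sole-absentee families per species
    genes_per_species: int | None = None  # optional budget check

    def __post_init__(self):
        for name in (
            "n_single_copy_core",
            "n_variable_copy_core",
            "n_dispensable",
            "n_species_specific",
            "n_singletons",
            "n_missing",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def simulate_cluster_table(
    config: SimulationConfig, composition: CategoryComposition | None = None
):
    """Cluster table with exactly the requested category composition.

    Returns ``(table, truth)`` where truth lists each family's planted
    category (and, for planted missing families, the absent species).
    Classification of the output reproduces the requested per-category
    counts exactly; planted missing families are recovered exactly.
    """
    comp = composition or CategoryComposition()
    rng = _rng(config, "cluster_table")
    species = tuple(sorted(config.species_tree.taxa))
    k = len(species)
    counters = {sp: 0 for sp in species}
    universes = {sp: set() for sp in species}
    families, truth_rows = {}, []
    fam_i = 0

    def new_gene(sp):
        counters[sp] += 1
        g = f"{sp}_g{counters[sp]:05d}"
        universes[sp].add(g)
        return g

    def add_family(by_sp_counts, category, absent=None):
        nonlocal fam_i
        fam_i += 1
        fid = f"FAM{fam_i:05d}"
        families[fid] = {
            sp: [new_gene(sp) for _ in range(n)] for sp, n in by_sp_counts.items() if n
        }
        truth_rows.append((fid, category, absent or ""))

    for _ in range(comp.n_single_copy_core):
        add_family({sp: 1 for sp in species}, "single_copy_core")
    for _ in range(comp.n_variable_copy_core):
        counts = {sp: 1 for sp in species}
        extra_sp = species[int(rng.integers(k))]
        counts[extra_sp] += int(rng.integers(1, 3))
        add_family(counts, "variable_copy_core")
    for sp in species:
        for _ in range(comp.n_missing):
            counts = {s: 1 for s in species if s != sp}
            add_family(counts, "dispensable", absent=sp)
    for _ in range(comp.n_dispensable):
        if k < 4:
            raise ValueError("dispensable families need >= 4 species")
        size = int(rng.integers(2, k - 1))  # 2..k-2 present: never sole-absentee
        present = rng.choice(k, size=size, replace=False)
        add_family({species[j]: 1 for j in present}, "dispensable")
    for sp in species:
        for _ in range(comp.n_species_specific):
            add_family({sp: int(rng.integers(2, 5))}, "species_specific")
    for sp in species:
        for _ in range(comp.n_singletons):
            new_gene(sp)  # in the universe, in no family
    if comp.genes_per_species is not None:
        over = {sp: len(universes[sp]) for sp in species
                if len(universes[sp]) > comp.genes_per_species}
        if over:
            raise ValueError(
                f"requested composition exceeds the per-species gene budget: {over}"
            )
    table = ClusterTable(families, species, universes)
    truth = pd.DataFrame(truth_rows, columns=["family_id", "category", "missing_in"])
    return table, truth


# --- coding pairs -----------------------------------------------------------

_SENSE_CODONS = sorted(
    c
    for c in ("".join(t) for t in product("ACGT", repeat=3))
    if c not in {"TAA", "TAG", "TGA"}
)


def _codon_neighbors():
    """Single-nucleotide neighbors of each sense codon, split syn/nonsyn."""
    from hymevol.divergence import _CODON_TABLE, _STOPS

    syn, nonsyn = {}, {}
    for c in _SENSE_CODONS:
        s_list, n_list = [], []
        for pos in range(3):
            for b in "ACGT":
                if b == c[pos]:
                    continue
                alt = c[:pos] + b + c[pos + 1 :]
                if alt in _STOPS:
                    continue
                (s_list if _CODON_TABLE[alt] == _CODON_TABLE[c] else n_list).append(alt)
        syn[c] = s_list
        nonsyn[c] = n_list
    return syn, nonsyn


_SYN_NEIGHBORS, _NONSYN_NEIGHBORS = _codon_neighbors()


def simulate_coding_pairs(config: SimulationConfig):
    """Aligned coding pairs with planted synonymous/nonsynonymous divergence.

    For each codon of a random sense-codon sequence, a synonymous change is
    planted with probability pS x (synonymous sites of the codon) and a
    nonsynonymous change with probability pN x (nonsynonymous sites), where
    pS and pN are the raw difference proportions implied by the dS/dN
    targets through the Jukes-Cantor map.  At most one change lands per
    codon and changes never create stops, so Nei-Gojobori estimates on the
    output recover the targets within sampling error.

    Returns ``(pairs, truth)``: pairs is a list of ``(pair_id, seq1,
    seq2)``; truth holds the planted difference counts per pair.
    """
    from hymevol.divergence import _SYN_SITES

    rng = _rng(config, "coding_pairs")
    pS = _jc_forward(config.ds_target)
    pN = _jc_forward(config.dn_target)
    pairs, rows = [], []
    codon_arr = np.array(_SENSE_CODONS)
    for i in range(config.n_pairs):
        pid = f"pair{i:05d}"
        codons1 = rng.choice(codon_arr, size=config.codons_per_pair)
        codons2 = codons1.copy()
        n_syn = n_nonsyn = 0
        u = rng.random(config.codons_per_pair)
        for j, c in enumerate(codons1):
            s_c = _SYN_SITES[c]
            q_syn = pS * s_c
            q_non = pN * (3.0 - s_c)
            if u[j] < q_syn and _SYN_NEIGHBORS[c]:
                codons2[j] = _SYN_NEIGHBORS[c][int(rng.integers(len(_SYN_NEIGHBORS[c])))]
                n_syn += 1
            elif u[j] < q_syn + q_non and _NONSYN_NEIGHBORS[c]:
                codons2[j] = _NONSYN_NEIGHBORS[c][
                    int(rng.integers(len(_NONSYN_NEIGHBORS[c])))
                ]
                n_nonsyn += 1
        pairs.append((pid, "".join(codons1), "".join(codons2)))
        rows.append((pid, n_syn, n_nonsyn, config.ds_target, config.dn_target))
    truth = pd.DataFrame(
        rows, columns=["pair_id", "n_syn_planted", "n_nonsyn_planted", "ds_target", "dn_target"]
    )
    return pairs, truth


def write_coding_pairs(pairs, path) -> None:
    """Write the paired CDS as interleaved FASTA (two records per pair)."""
    records = {}
    for pid, s1, s2 in pairs:
        records[f"{pid}|line1"] = s1
        records[f"{pid}|line2"] = s2
    write_fasta(records, path)
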