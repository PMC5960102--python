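"""Nei-Gojobori divergence, variant classification and selection summaries."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from hymevol import divergence as dv
from hymevol.annotation import GeneModel
from hymevol.simulate import SimulationConfig, simulate_coding_pairs

# --- independent brute-force oracle ----------------------------------------

_CODE = {}
_BASES = "TCAG"
_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for i, (b1, b2, b3) in enumerate(itertools.product(_BASES, repeat=3)):
    _CODE[b1 + b2 + b3] = _AAS[i]


def _oracle_sites(codon):
    """Synonymous site count of one codon by direct enumeration."""
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if _CODE[alt] != "*" and _CODE[alt] == _CODE[codon]:
                syn += 1
        s += syn / 3
    return s


def _oracle_diffs(c1, c2):
    """Pathway-averaged syn/nonsyn differences by explicit enumeration."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    valid, fallback = [], []
    for order in itertools.permutations(diff):
        cur, sd, nd, ok = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if _CODE[nxt] == "*":
                ok = False
            if _CODE[nxt] != "*" and _CODE[cur] != "*" and _CODE[cur] == _CODE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (valid if ok else fallback).append((sd, nd))
    use = valid or fallback
    return (
        sum(x[0] for x in use) / len(use),
        sum(x[1] for x in use) / len(use),
    )


def _oracle_ng(seq1, seq2):
    codons = [
        (seq1[i : i + 3], seq2[i : i + 3]) for i in range(0, len(seq1) - 2, 3)
    ]
    codons = [
        (a, b)
        for a, b in codons
        if set(a + b) <= set("ACGT") and _CODE[a] != "*" and _CODE[b] != "*"
    ]
    S = sum(_oracle_sites(a) + _oracle_sites(b) for a, b in codons) / 2
    N = 3 * len(codons) - S
    Sd = Nd = 0.0
    for a, b in codons:
        sd, nd = _oracle_diffs(a, b)
        Sd += sd
        Nd += nd
    return N, S, Nd, Sd


SENSE = [c for c in _CODE if _CODE[c] != "*"]


def test_identical_sequences_zero_divergence():
    seq = "ATGAAACCCGGG"
    stats = dv.nei_gojobori(seq, seq)
    assert stats.dN == 0.0 and stats.dS == 0.0
    assert stats.Nd == 0.0 and stats.Sd == 0.0


def test_symmetry_under_sequence_swap(rng):
    for _ in range(10):
        codons1 = rng.choice(SENSE, 50)
        codons2 = codons1.copy()
        idx = rng.choice(50, 10, replace=False)
        codons2[idx] = rng.choice(SENSE, 10)
        s1, s2 = "".join(codons1), "".join(codons2)
        if any(c in dv._STOPS for c in [s2[i:i+3] for i in range(0, 150, 3)]):
            continue
        a = dv.nei_gojobori(s1, s2)
        b = dv.nei_gojobori(s2, s1)
        assert a.N == pytest.approx(b.N)
        assert a.Sd == pytest.approx(b.Sd)
        assert a.pN == pytest.approx(b.pN)


def test_site_counts_sum_to_three_per_codon(rng):
    for _ in range(20):
        seq = "".join(rng.choice(SENSE, 40))
        stats = dv.nei_gojobori(seq, seq)
        assert stats.N + stats.S == pytest.approx(3 * stats.n_codons, abs=1e-6)


def test_matches_pathway_enumeration_oracle(rng):
    # >=100 random pairs of ~30 codons against the independent oracle
    for _ in range(100):
        codons1 = rng.choice(SENSE, 30)
        codons2 = codons1.copy()
        n_mut = int(rng.integers(1, 12))
        for j in rng.choice(30, n_mut, replace=False):
            codons2[j] = rng.choice(SENSE)
        s1, s2 = "".join(codons1), "".join(codons2)
        got = dv.nei_gojobori(s1, s2)
        N, S, Nd, Sd = _oracle_ng(s1, s2)
        assert got.N == pytest.approx(N, abs=1e-9)
        assert got.S == pytest.approx(S, abs=1e-9)
        assert got.Nd == pytest.approx(Nd, abs=1e-9)
        assert got.Sd == pytest.approx(Sd, abs=1e-9)


def test_jukes_cantor_properties():
    assert dv.jukes_cantor(0.0) == 0.0
    assert dv.jukes_cantor(0.75) is None
    p = 1e-4
    d = dv.jukes_cantor(p)
    assert d >= p
    assert d == pytest.approx(p, abs=1e-6)
    for p in (0.01, 0.1, 0.3, 0.5):
        assert dv.jukes_cantor(p) >= p


def test_ambiguous_and_stop_codons_skipped_and_counted():
    s1 = "ATGNNNAAA"
    s2 = "ATGAAATAA"  # middle codon ambiguous in s1, third is a stop in s2
    stats = dv.nei_gojobori(s1, s2)
    assert stats.n_codons == 1
    assert stats.n_skipped == 2


def test_simulator_recovery_at_default_conditions():
    cfg = SimulationConfig(seed=61, n_pairs=30, codons_per_pair=3000)
    pairs, truth = simulate_coding_pairs(cfg)
    stats = [dv.nei_gojobori(s1, s2, pid) for pid, s1, s2 in pairs]
    agg = dv.aggregate_divergence(stats)
    assert agg.mean_dS == pytest.approx(cfg.ds_target, abs=3 * max(agg.se_dS, 1e-4))
    assert agg.mean_dN == pytest.approx(cfg.dn_target, abs=3 * max(agg.se_dN, 1e-4))


def test_neutral_targets_give_ratio_near_one():
    cfg = SimulationConfig(seed=63, n_pairs=8, codons_per_pair=20000,
                           ds_target=0.05, dn_target=0.05)
    pairs, _ = simulate_coding_pairs(cfg)
    stats = [dv.nei_gojobori(s1, s2, pid) for pid, s1, s2 in pairs]
    ratios = [s.ratio for s in stats if s.ratio is not None]
    assert np.mean(ratios) == pytest.approx(1.0, abs=0.1)


def test_zero_targets_give_identical_sequences():
    cfg = SimulationConfig(seed=65, n_pairs=5, codons_per_pair=200,
                           ds_target=0.0, dn_target=0.0)
    pairs, _ = simulate_coding_pairs(cfg)
    for _, s1, s2 in pairs:
        assert s1 == s2


def test_aggregate_se_shrinks_with_gene_count():
    cfg_small = SimulationConfig(seed=67, n_pairs=10, codons_per_pair=500)
    cfg_big = SimulationConfig(seed=67, n_pairs=160, codons_per_pair=500)
    agg_s = dv.aggregate_divergence(
        [dv.nei_gojobori(s1, s2) for _, s1, s2 in simulate_coding_pairs(cfg_small)[0]]
    )
    agg_b = dv.aggregate_divergence(
        [dv.nei_gojobori(s1, s2) for _, s1, s2 in simulate_coding_pairs(cfg_big)[0]]
    )
    assert agg_b.se_dS < agg_s.se_dS


# --- variant classification -------------------------------------------------

def test_variant_silent_missense_nonsense():
    # plus-strand gene, CDS = positions 1..9 of contig "GCTGCAAAA"
    genome = {"c": "GCTGCAAAATTTT"}
    model = GeneModel("g", "g.t", "c", "+", exons=[(1, 9)], cds=[(1, 9, "0")])
    silent = dv.classify_variant("c", 3, "T", "C", [model], genome)  # GCT->GCC Ala
    assert silent.effect == dv.EFFECT_SILENT and silent.region == dv.REGION_CODING
    missense = dv.classify_variant("c", 1, "G", "A", [model], genome)  # GCT->ACT
    assert missense.effect == dv.EFFECT_MISSENSE
    stop = dv.classify_variant("c", 7, "A", "T", [model], genome)  # AAA->TAA
    assert stop.effect == dv.EFFECT_NONSENSE


def test_variant_minus_strand_effect():
    # minus strand gene: genomic TTTCAT reverse-complements to ATGAAA
    genome = {"c": "TTTCATGGG"}
    model = GeneModel("g", "g.t", "c", "-", exons=[(1, 6)], cds=[(1, 6, "0")])
    # genomic pos 6 T->C: coding ATGAAA -> GTGAAA? pos 6 is first coding base
    rec = dv.classify_variant("c", 6, "T", "C", [model], genome)
    assert rec.effect == dv.EFFECT_MISSENSE  # Met -> Val
    # genomic pos 1 T->C: coding last base A->G, AAA->AAG both Lys
    rec2 = dv.classify_variant("c", 1, "T", "C", [model], genome)
    assert rec2.effect == dv.EFFECT_SILENT


def test_variant_regions_and_precedence():
    genome = {"c": "A" * 60}
    model = GeneModel(
        "g", "g.t", "c", "+",
        exons=[(11, 20), (31, 40)],
        cds=[(14, 20, "0"), (31, 34, "0")],
        utrs=[(11, 13, "five_prime_UTR"), (35, 40, "three_prime_UTR")],
    )
    assert dv.classify_variant("c", 12, "A", "G", [model], genome).region == dv.REGION_UTR
    assert dv.classify_variant("c", 25, "A", "G", [model], genome).region == dv.REGION_INTRON
    assert dv.classify_variant("c", 5, "A", "G", [model], genome).region == dv.REGION_INTERGENIC
    assert dv.classify_variant("c", 15, "A", "G", [model], genome).region == dv.REGION_CODING


def test_indel_frameshift_rule():
    genome = {"c": "GCTGCAAAATTTT"}
    model = GeneModel("g", "g.t", "c", "+", exons=[(1, 9)], cds=[(1, 9, "0")])
    fs = dv.classify_variant("c", 2, "CT", "C", [model], genome)  # 1-bp del
    assert fs.var_class == dv.INDEL and fs.effect == dv.EFFECT_FRAMESHIFT
    inframe = dv.classify_variant("c", 1, "GCTG", "G", [model], genome)  # 3-bp del
    assert inframe.effect == dv.EFFECT_INFRAME


def test_reference_mismatch_is_error():
    genome = {"c": "GCTGCAAAA"}
    model = GeneModel("g", "g.t", "c", "+", exons=[(1, 9)], cds=[(1, 9, "0")])
    with pytest.raises(ValueError, match="mismatch"):
        dv.classify_variant("c", 3, "A", "C", [model], genome)


def test_every_variant_gets_exactly_one_region(rng):
    genome = {"c": "".join(rng.choice(list("ACGT"), 200))}
    model = GeneModel(
        "g", "g.t", "c", "+", exons=[(21, 60), (101, 140)],
        cds=[(31, 60, "0"), (101, 120, "0")],
        utrs=[(21, 30, "five_prime_UTR"), (121, 140, "three_prime_UTR")],
    )
    regions = set()
    variants = pd.DataFrame(
        [
            ("c", int(p), genome["c"][p - 1], "A" if genome["c"][p - 1] != "A" else "G")
            for p in rng.choice(np.arange(1, 201), 60, replace=False)
        ],
        columns=["seqid", "pos", "ref", "alt"],
    )
    annotated = dv.classify_variants(variants, [model], genome)
    assert len(annotated) == 60
    valid = {dv.REGION_CODING, dv.REGION_UTR, dv.REGION_INTRON, dv.REGION_INTERGENIC,
             dv.REGION_OTHER_GENIC}
    assert set(annotated.region) <= valid
    # coding effect only inside coding regions
    outside = annotated[annotated.region != dv.REGION_CODING]
    assert (outside.effect == dv.EFFECT_NONE).all()


def test_missense_silent_ratio():
    df = pd.DataFrame({"effect": [dv.EFFECT_MISSENSE] * 3 + [dv.EFFECT_SILENT] * 6})
    assert dv.missense_silent_ratio(df) == 0.5
    no_missense = pd.DataFrame({"effect": [dv.EFFECT_SILENT] * 4})
    assert dv.missense_silent_ratio(no_missense) == 0.0
    with pytest.raises(ValueError):
        dv.missense_silent_ratio(pd.DataFrame({"effect": [dv.EFFECT_MISSENSE]}))


def test_top_divergence_selection_and_ties(rng):
    rates = {f"g{i}": i for i in range(100)}
    lengths = {g: 1 for g in rates}
    selected, tied = dv.top_divergence_genes(rates, lengths, fraction=0.05)
    assert selected == frozenset(f"g{i}" for i in range(95, 100))
    assert not tied
    equal = {f"g{i}": 5 for i in range(10)}
    selected, tied = dv.top_divergence_genes(equal, {g: 1 for g in equal})
    assert selected == frozenset(equal) and tied


def test_top_divergence_matches_sort_oracle(rng):
    for _ in range(50):
        n = int(rng.integers(5, 80))
        counts = {f"g{i}": int(rng.integers(0, 30)) for i in range(n)}
        lengths = {g: int(rng.integers(50, 500)) for g in counts}
        selected, _ = dv.top_divergence_genes(counts, lengths, fraction=0.10)
        rates = {g: counts[g] / lengths[g] for g in counts}
        k = math.ceil(0.10 * n)
        cutoff = sorted(rates.values(), reverse=True)[k - 1]
        oracle = {g for g, r in rates.items() if r >= cutoff}
        assert set(selected) == oracle
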