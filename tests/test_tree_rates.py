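"""Place ranking, rank-discrepancy scoring, binning and overlap accounting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hymevol import tree_rates as tr
from hymevol.phylo import CHALCIDS, default_phylogeny
from hymevol.simulate import SimulationConfig, simulate_gene_trees


# --- reading and distances --------------------------------------------------

def _write_trees(tmp_path, lines):
    path = tmp_path / "trees.txt"
    path.write_text("".join(f"{oid}\t{nwk}\n" for oid, nwk in lines))
    return path


def test_read_gene_trees_roundtrip(tmp_path, small_config):
    tree_set, _ = simulate_gene_trees(small_config)
    path = tmp_path / "trees.txt"
    tree_set.write(path)
    loaded = tr.read_gene_trees(path, small_config.species_tree)
    assert len(loaded) == len(tree_set)


def test_read_gene_trees_reports_missing_and_extra_leaves(tmp_path, phylo):
    good = (
        "(Athalia:1,(Orussus:1,(Apis:1,(Microplitis:1,(Trichogramma:1,"
        "(Ceratosolen:1,(Copidosoma:1,Nasonia:1):1):1):1):1):1):1);"
    )
    missing = good.replace("Copidosoma:1,", "")
    path = _write_trees(tmp_path, [("OG1", good), ("OG2", missing)])
    with pytest.raises(tr.GeneTreeError, match="OG2.*Copidosoma"):
        tr.read_gene_trees(path, phylo)
    # skip_bad keeps the valid tree
    with pytest.warns(UserWarning):
        loaded = tr.read_gene_trees(path, phylo, skip_bad=True)
    assert set(loaded.trees) == {"OG1"}


def test_read_gene_trees_rejects_negative_lengths(tmp_path, phylo):
    bad = (
        "(Athalia:1,(Orussus:1,(Apis:1,(Microplitis:1,(Trichogramma:-0.5,"
        "(Ceratosolen:1,(Copidosoma:1,Nasonia:1):1):1):1):1):1):1);"
    )
    path = _write_trees(tmp_path, [("OG9", bad)])
    with pytest.raises(tr.GeneTreeError, match="OG9.*negative"):
        tr.read_gene_trees(path, phylo)


def test_distances_match_simulator_ground_truth(small_config):
    tree_set, truth = simulate_gene_trees(small_config)
    dist = tr.root_to_anchor_distances(tree_set, small_config.species_tree)
    merged = dist.merge(truth, on=["ortholog_id", "species"], suffixes=("", "_t"))
    assert np.allclose(merged.order_dist, merged.order_dist_t, atol=1e-9)
    assert np.allclose(merged.base_dist, merged.base_dist_t, atol=1e-9)
    chalcid = merged[merged.species.isin(CHALCIDS)]
    assert np.allclose(chalcid.clade_dist, chalcid.clade_dist_t, atol=1e-9)


def test_distance_additivity_for_clade_members(small_config):
    tree_set, _ = simulate_gene_trees(small_config)
    dist = tr.root_to_anchor_distances(tree_set, small_config.species_tree)
    chalcid = dist[dist.species.isin(CHALCIDS)]
    assert np.allclose(
        chalcid.order_dist, chalcid.clade_dist + chalcid.base_dist, atol=1e-9
    )


def test_hand_computed_four_leaf_distances(tmp_path):
    # all branches 0.1; clade = {C, D}: each clade member is 0.1 from the MRCA
    import dendropy

    from hymevol.phylo import OrthologTreeSet, SpeciesPhylogeny

    nwk = "(A:0.1,(B:0.1,(C:0.1,D:0.1):0.1):0.1);"
    tree = dendropy.Tree.get(data=nwk, schema="newick", rooting="default-rooted")
    phylo = SpeciesPhylogeny(
        tree=tree,
        clade_members=frozenset({"C", "D"}),
        order_members=frozenset({"B", "C", "D"}),
    )
    gene_tree = dendropy.Tree.get(data=nwk, schema="newick", rooting="default-rooted")
    dist = tr.root_to_anchor_distances(
        OrthologTreeSet(trees={"OG1": gene_tree}), phylo
    )
    by_sp = dist.set_index("species")
    assert by_sp.loc["C", "clade_dist"] == pytest.approx(0.1)
    assert by_sp.loc["D", "clade_dist"] == pytest.approx(0.1)
    assert by_sp.loc["C", "base_dist"] == pytest.approx(0.1)
    assert by_sp.loc["C", "order_dist"] == pytest.approx(0.2)


# --- place table ------------------------------------------------------------

def _toy_distances(values_by_ortholog):
    rows = [
        (oid, sp, v, v + 1.0, 1.0)
        for oid, by_sp in values_by_ortholog.items()
        for sp, v in by_sp.items()
    ]
    return pd.DataFrame(
        rows, columns=["ortholog_id", "species", "clade_dist", "order_dist", "base_dist"]
    )


def test_place_table_simple_ordering():
    dist = _toy_distances({"OG1": {"w": 0.5, "x": 0.3, "y": 0.2, "z": 0.1}})
    pt = tr.place_table(dist, ["w", "x", "y", "z"])
    assert pt.places.loc["OG1"].tolist() == [1, 2, 3, 4]
    assert not pt.tied_orthologs


def test_place_table_flags_and_breaks_ties_by_name():
    dist = _toy_distances({"OG1": {"b": 0.5, "a": 0.5, "c": 0.1}})
    pt = tr.place_table(dist, ["a", "b", "c"])
    assert pt.tied_orthologs == ("OG1",)
    assert pt.places.loc["OG1", "a"] == 1  # name order breaks the tie
    assert pt.places.loc["OG1", "b"] == 2


def test_place_table_marginals_sum_to_n(small_config):
    tree_set, _ = simulate_gene_trees(small_config)
    dist = tr.root_to_anchor_distances(tree_set, small_config.species_tree)
    pt = tr.place_table(dist, CHALCIDS)
    n = small_config.n_orthologs
    assert (pt.counts.sum(axis=1) == n).all()  # per species over places
    assert (pt.counts.sum(axis=0) == n).all()  # per place over species


def test_place_table_matches_brute_force_sort_oracle(rng):
    species = ["s1", "s2", "s3", "s4"]
    for _ in range(100):
        n = int(rng.integers(3, 15))
        data = {
            f"OG{i}": {sp: float(rng.random()) for sp in species}
            for i in range(n)
        }
        pt = tr.place_table(_toy_distances(data), species)
        for oid, by_sp in data.items():
            # independent oracle: rank by explicit descending sort
            expected = {
                sp: 1 + sorted(by_sp.values(), reverse=True).index(v)
                for sp, v in by_sp.items()
            }
            assert pt.places.loc[oid].to_dict() == expected


def test_expected_place_count():
    assert tr.expected_place_count(1311, 4) == (327.75, 328)
    assert tr.expected_place_count(100, 4) == (25.0, 25)
    exact, _ = tr.expected_place_count(1311, 7)
    assert exact == pytest.approx(187.2857, abs=1e-4)
    with pytest.raises(ValueError):
        tr.expected_place_count(1311, 0)


# --- normalisation and ranks ------------------------------------------------

def test_normalize_branch_values():
    assert tr.normalize_branch(0.2, 0.1) == pytest.approx(2.0)
    assert tr.normalize_branch(0.0, 0.1) == 0.0
    with pytest.raises(ValueError):
        tr.normalize_branch(0.2, 0.0)


def test_normalized_lengths_excludes_zero_base_with_warning():
    dist = _toy_distances({"OG1": {"a": 0.2}, "OG2": {"a": 0.3}})
    dist.loc[dist.ortholog_id == "OG2", "base_dist"] = 0.0
    with pytest.warns(UserWarning, match="OG2"):
        out = tr.normalized_lengths(dist)
    assert set(out.ortholog_id) == {"OG1"}


def test_scale_invariance_of_places_ranks_and_normalisation(small_config):
    tree_set, _ = simulate_gene_trees(small_config)
    dist = tr.root_to_anchor_distances(tree_set, small_config.species_tree)
    # scale one gene tree's branches by a constant
    scaled = dist.copy()
    target = scaled.ortholog_id.iloc[0]
    cols = ["clade_dist", "order_dist", "base_dist"]
    scaled.loc[scaled.ortholog_id == target, cols] *= 7.3
    pt0 = tr.place_table(dist, CHALCIDS)
    pt1 = tr.place_table(scaled, CHALCIDS)
    assert pt0.places.loc[target].equals(pt1.places.loc[target])
    n0 = tr.normalized_lengths(dist)
    n1 = tr.normalized_lengths(scaled)
    assert np.allclose(
        n0[n0.ortholog_id == target].normalized_length,
        n1[n1.ortholog_id == target].normalized_length,
        equal_nan=True,  # non-clade species carry no clade distance
    )


def test_assign_ranks_orientation_and_ties():
    assert tr.assign_ranks([0.1, 0.3, 0.2]).tolist() == [1, 3, 2]
    # ties: input order wins (callers order by ortholog id)
    assert tr.assign_ranks([0.5, 0.5, 0.1]).tolist() == [2, 3, 1]
    with pytest.raises(ValueError):
        tr.assign_ranks([0.1, float("nan")])


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50))
def test_assign_ranks_is_permutation(values):
    ranks = tr.assign_ranks(values)
    assert sorted(ranks) == list(range(1, len(values) + 1))


def test_rank_change_score_worked_example():
    assert tr.rank_change_score(10, 1000) == 990
    assert tr.rank_change_score(500, 500) == 0
    assert tr.rank_change_score(1000, 10) == -990
    with pytest.raises(ValueError):
        tr.rank_change_score(0, 5)


def test_median_rank():
    assert tr.median_rank([10, 20, 30]) == 20
    assert tr.median_rank([10, 20]) == 15
    assert tr.median_rank([5, 5, 5, 5]) == 5
    with pytest.raises(ValueError):
        tr.median_rank([])


def test_rank_table_columns_are_permutations(small_config):
    tree_set, _ = simulate_gene_trees(small_config)
    dist = tr.root_to_anchor_distances(tree_set, small_config.species_tree)
    ranks = tr.rank_table(dist, CHALCIDS)
    n = small_config.n_orthologs
    for col in ranks.columns:
        assert sorted(ranks[col]) == list(range(1, n + 1))


# --- binning and selection --------------------------------------------------

def _random_scores(rng, n):
    ids = [f"OG{i:04d}" for i in range(n)]
    scores = pd.Series(rng.integers(-n, n, size=n), index=ids, dtype=float)
    base = pd.Series(rng.permutation(n) + 1, index=ids)
    return scores, base


def test_bin_and_select_1311_bin_arithmetic(rng):
    scores, base = _random_scores(rng, 1311)
    sel = tr.bin_and_select(scores, base, bin_size=100, fraction=0.10)
    # 13 full bins contribute 10 fast + 10 slow, remainder bin of 11 adds 1 + 1
    assert len(sel.fast) == 13 * 10 + 1
    assert len(sel.slow) == 13 * 10 + 1
    assert sel.bins["bin"].max() == 13


def test_bin_and_select_all_equal_scores_flagged():
    ids = [f"OG{i}" for i in range(20)]
    scores = pd.Series(0.0, index=ids)
    base = pd.Series(range(1, 21), index=ids)
    sel = tr.bin_and_select(scores, base, bin_size=10, fraction=0.10)
    assert sel.tied_bins == (0, 1)


def _brute_force_select(scores, base, bin_size, fraction):
    import math

    order = sorted(scores.index, key=lambda g: (base[g], g))
    fast, slow = set(), set()
    for start in range(0, len(order), bin_size):
        members = order[start : start + bin_size]
        k = max(1, int(math.floor(fraction * len(members) + 0.5)))
        fast.update(sorted(members, key=lambda g: (-scores[g], g))[:k])
        slow.update(sorted(members, key=lambda g: (scores[g], g))[:k])
    return fast, slow


def test_bin_and_select_matches_brute_force_oracle(rng):
    for _ in range(100):
        n = int(rng.integers(5, 120))
        bin_size = int(rng.integers(2, 40))
        scores, base = _random_scores(rng, n)
        sel = tr.bin_and_select(scores, base, bin_size=bin_size, fraction=0.10)
        fast, slow = _brute_force_select(scores, base, bin_size, 0.10)
        assert set(sel.fast) == fast
        assert set(sel.slow) == slow


# --- overlaps ---------------------------------------------------------------

def test_overlap_partition_small_example():
    out = tr.overlap_partition({1, 2}, {2, 3}, {2})
    assert out == {
        "A_only": 1, "B_only": 1, "C_only": 0,
        "AB": 0, "AC": 0, "BC": 0, "ABC": 1,
    }


def test_overlap_partition_identical_sets():
    out = tr.overlap_partition({1, 2}, {1, 2}, {1, 2})
    assert out["ABC"] == 2
    assert sum(out.values()) == 2


@settings(max_examples=50, deadline=None)
@given(
    st.sets(st.integers(0, 30)),
    st.sets(st.integers(0, 30)),
    st.sets(st.integers(0, 30)),
)
def test_overlap_partition_sums_to_union(a, b, c):
    out = tr.overlap_partition(a, b, c)
    assert sum(out.values()) == len(a | b | c)
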