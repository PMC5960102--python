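"""Root-to-ancestor branch lengths, place ranking and rank-discrepancy scores.

Within each orthologous group the species are *placed* by their branch
length from the clade ancestor (1st place = longest branch = most amino
acid change since that ancestor).  Aggregating places over all orthologs
and comparing against the equal-probability null reveals lineages with
genome-wide accelerated protein evolution.

To find individual proteins evolving unusually fast or slowly in a lineage,
each protein also receives a *within-genome rank* (rank ``N`` = longest
branch among the ``N`` core proteins of that genome) and a *base rank*
(same, by the clade-root-to-order-root distance, a proxy for the protein's
baseline rate).  The *rank-change score* ``comparison_rank - base_rank`` is
positive for proteins relatively faster in the focal lineage than their
baseline predicts; selection of the extreme scores is done within
consecutive base-rank bins so no baseline-rate stratum dominates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hymevol.phylo import (
    OrthologTreeSet,
    SpeciesPhylogeny,
    leaf_names,
    mrca,
    parse_gene_tree,
    path_length,
    read_tree_lines,
)

_ADDITIVITY_TOL = 1e-9


class GeneTreeError(ValueError):
    """A gene tree failed validation against the species phylogeny."""


def read_gene_trees(
    path, phylogeny: SpeciesPhylogeny, skip_bad: bool = False
) -> OrthologTreeSet:
    """Read per-ortholog gene trees from an ``id<TAB>newick`` file.

    Every tree must contain exactly the species phylogeny's taxa and have
    non-negative branch lengths.  Offending trees are reported with their
    ortholog id; the whole read aborts unless ``skip_bad`` is set, in which
    case bad trees are dropped with a warning.
    """
    expected = set(phylogeny.taxa)
    trees, errors = {}, []
    for oid, nwk in read_tree_lines(path).items():
        try:
            tree = parse_gene_tree(nwk)
        except Exception as exc:  # dendropy raises various parse errors
            errors.append(f"{oid}: malformed Newick ({exc})")
            continue
        got = leaf_names(tree)
        if got != expected:
            missing = sorted(expected - got)
            extra = sorted(got - expected)
            parts = []
            if missing:
                parts.append(f"missing taxa {missing}")
            if extra:
                parts.append(f"unexpected taxa {extra}")
            errors.append(f"{oid}: {'; '.join(parts)}")
            continue
        neg = [
            e.length
            for e in tree.preorder_edge_iter()
            if e.length is not None and e.length < 0
        ]
        if neg:
            errors.append(f"{oid}: negative branch length {min(neg)}")
            continue
        trees[oid] = tree
    if errors:
        msg = "invalid gene trees:\n  " + "\n  ".join(errors)
        if not skip_bad:
            raise GeneTreeError(msg)
        warnings.warn(msg + "\n(skipped)", stacklevel=2)
    return OrthologTreeSet(trees=trees)


def root_to_anchor_distances(
    tree_set: OrthologTreeSet, phylogeny: SpeciesPhylogeny
) -> pd.DataFrame:
    """Per-(ortholog, species) distances to the clade and order anchors.

    Returns a DataFrame with columns ``ortholog_id, species, clade_dist,
    order_dist, base_dist``.  ``clade_dist`` is filled only for clade
    members; ``base_dist`` (clade root to order root) is shared by all rows
    of one ortholog.  For clade members the additivity identity
    ``order_dist = clade_dist + base_dist`` holds by construction and is
    asserted to 1e-9.
    """
    clade_set = set(phylogeny.clade_members)
    order_set = set(phylogeny.order_members)
    rows = []
    for oid, tree in tree_set:
        clade_node = mrca(tree, clade_set)
        order_node = mrca(tree, order_set)
        base = path_length(clade_node, order_node)
        for leaf in tree.leaf_node_iter():
            sp = leaf.taxon.label
            if sp not in order_set:
                continue
            order_d = path_length(leaf, order_node)
            clade_d = math.nan
            if sp in clade_set:
                clade_d = path_length(leaf, clade_node)
                if abs(order_d - (clade_d + base)) > _ADDITIVITY_TOL:
                    raise GeneTreeError(
                        f"{oid}/{sp}: order distance not additive "
                        f"({order_d} != {clade_d} + {base})"
                    )
            rows.append((oid, sp, clade_d, order_d, base))
    return pd.DataFrame(
        rows,
        columns=["ortholog_id", "species", "clade_dist", "order_dist", "base_dist"],
    )


@dataclass
class PlaceTable:
    """Places (1 = longest branch) per ortholog and their per-species tally."""

    places: pd.DataFrame  # index ortholog_id, columns species, values 1..k
    counts: pd.DataFrame  # index species, columns place 1..k
    tied_orthologs: tuple = ()

    @property
    def n_orthologs(self) -> int:
        return len(self.places)


def place_table(distances: pd.DataFrame, clade_members, column: str = "clade_dist") -> PlaceTable:
    """Score branch lengths within each orthologous group.

    Within each ortholog the ``clade_members`` are sorted by descending
    ``column``; the longest branch takes 1st place.  Exact ties are broken
    deterministically by species-name order and the affected orthologs are
    flagged in ``tied_orthologs``.
    """
    members = sorted(clade_members)
    k = len(members)
    sub = distances[distances.species.isin(members)]
    wide = sub.pivot(index="ortholog_id", columns="species", values=column)
    if wide[members].isna().any().any():
        bad = wide[wide[members].isna().any(axis=1)].index.tolist()
        raise ValueError(f"missing distances for orthologs {bad}")
    place_rows, tied = {}, []
    for oid, row in wide.iterrows():
        vals = [(-row[sp], sp) for sp in members]  # descending dist, name tiebreak
        order = sorted(vals)
        if len({v for v, _ in vals}) < k:
            tied.append(oid)
        place_rows[oid] = {sp: i + 1 for i, (_, sp) in enumerate(order)}
    places = pd.DataFrame.from_dict(place_rows, orient="index")[members]
    places.index.name = "ortholog_id"
    counts = pd.DataFrame(
        {
            sp: [(places[sp] == p).sum() for p in range(1, k + 1)]
            for sp in members
        },
        index=pd.Index(range(1, k + 1), name="place"),
    ).T
    return PlaceTable(places=places, counts=counts, tied_orthologs=tuple(tied))


def expected_place_count(n_orthologs: int, k_species: int) -> tuple[float, int]:
    """Expected per-species count at any one place under the uniform null.

    Returns ``(n/k, nearest-integer rendering)``; e.g. 1311 orthologs over
    four candidate species give (327.75, 328).
    """
    if k_species < 2:
        raise ValueError("need at least two species")
    if n_orthologs < 1:
        raise ValueError("need at least one ortholog")
    exact = n_orthologs / k_species
    return exact, int(math.floor(exact + 0.5))


def normalize_branch(clade_dist: float, base_dist: float) -> float:
    """Species-to-clade-root distance normalised by the clade-to-order stem.

    Division by the clade-root-to-order-root distance removes each
    protein's baseline rate.  A zero ``base_dist`` is degenerate and must
    be excluded upstream (see :func:`normalized_lengths`).
    """
    if base_dist <= 0:
        raise ValueError("base_dist must be positive; exclude degenerate orthologs")
    return clade_dist / base_dist


def normalized_lengths(distances: pd.DataFrame) -> pd.DataFrame:
    """Add a ``normalized_length`` column; drop (and warn about) orthologs
    whose clade-to-order stem has zero length."""
    out = distances.copy()
    zero = out.base_dist <= 0
    if zero.any():
        dropped = sorted(out.loc[zero, "ortholog_id"].unique())
        warnings.warn(
            f"excluded {len(dropped)} ortholog(s) with zero-length "
            f"clade-to-order stem: {dropped[:10]}...",
            stacklevel=2,
        )
        out = out[~out.ortholog_id.isin(dropped)]
    out = out.assign(normalized_length=out.clade_dist / out.base_dist)
    return out


def assign_ranks(values, direction: str = "ascending") -> np.ndarray:
    """Rank values 1..N; rank 1 = smallest (shortest branch) by default.

    With the default orientation a long branch gets a high rank, so a
    positive rank-change score marks a protein relatively *faster* in the
    comparison than its baseline — matching the worked "+990" convention.
    Ties are broken by input order (callers sort by ortholog id), making
    the result a deterministic permutation of 1..N.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("need a non-empty 1-D value vector")
    if not np.isfinite(arr).all():
        raise ValueError("non-finite values cannot be ranked")
    if direction == "descending":
        arr = -arr
    elif direction != "ascending":
        raise ValueError("direction must be 'ascending' or 'descending'")
    order = np.argsort(arr, kind="stable")
    ranks = np.empty(arr.size, dtype=int)
    ranks[order] = np.arange(1, arr.size + 1)
    return ranks


def rank_table(distances: pd.DataFrame, clade_members) -> pd.DataFrame:
    """Within-genome ranks per clade member plus the shared base rank.

    Rows are orthologs (sorted by id, which also breaks ties); columns are
    one within-genome rank per clade member (by that species'
    clade-anchored distance) and ``base_rank`` (by the clade-to-order stem
    length).  Rank 1 is the shortest branch.
    """
    members = sorted(clade_members)
    sub = distances[distances.species.isin(members)]
    wide = sub.pivot(index="ortholog_id", columns="species", values="clade_dist")
    wide = wide.sort_index()
    out = pd.DataFrame(index=wide.index)
    for sp in members:
        out[sp] = assign_ranks(wide[sp].to_numpy())
    base = (
        distances[["ortholog_id", "base_dist"]]
        .drop_duplicates("ortholog_id")
        .set_index("ortholog_id")
        .sort_index()
    )
    out["base_rank"] = assign_ranks(base["base_dist"].to_numpy())
    return out


def rank_change_score(base_rank: float, comparison_rank: float, n: int | None = None) -> int:
    """``comparison_rank - base_rank``, rounded half away from zero.

    A protein with base rank 10 (short baseline branch) and comparison
    rank 1000 (long branch in the focal lineage) scores +990.  Half-integer
    comparison ranks arise only from medians over an even species count.
    """
    for r in (base_rank, comparison_rank):
        if r < 1 or (n is not None and r > n):
            raise ValueError(f"rank {r} outside 1..{n}")
    diff = comparison_rank - base_rank
    return int(math.copysign(math.floor(abs(diff) + 0.5), diff)) if diff else 0


def median_rank(ranks) -> float:
    """Median of per-species ranks; even counts give the middle-two mean."""
    arr = np.asarray(list(ranks), dtype=float)
    if arr.size == 0:
        raise ValueError("median of empty rank set")
    return float(np.median(arr))


@dataclass
class BinSelection:
    fast: frozenset
    slow: frozenset
    bins: pd.DataFrame  # per ortholog: bin index, score, base_rank
    tied_bins: tuple = ()  # bins where the selection cut fell inside a tie


def bin_and_select(
    scores: pd.Series, base_ranks: pd.Series, bin_size: int = 100, fraction: float = 0.10
) -> BinSelection:
    """Select extreme rank-change scores within consecutive base-rank bins.

    Proteins are ordered by base rank and cut into consecutive bins of
    ``bin_size`` (the final bin holds the remainder).  Within each bin the
    ``fraction`` with the most positive scores become "fast" and the most
    negative "slow"; the per-bin count is ``round(fraction * occupancy)``
    with a floor of 1 so small remainder bins still contribute.  Ties at a
    cut are broken by ortholog id and the affected bins flagged.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    scores = scores.sort_index()
    base_ranks = base_ranks.sort_index()
    if not scores.index.equals(base_ranks.index):
        raise ValueError("scores and base_ranks must share ortholog ids")
    order = base_ranks.sort_values(kind="stable").index
    bin_idx = pd.Series(np.arange(len(order)) // bin_size, index=order, name="bin")
    fast, slow, tied_bins = set(), set(), []
    for b, ids in bin_idx.groupby(bin_idx).groups.items():
        occ = len(ids)
        n_sel = max(1, int(math.floor(fraction * occ + 0.5)))
        sub = scores.loc[ids].sort_index()  # id order = deterministic tiebreak
        by_desc = sub.sort_values(ascending=False, kind="stable")
        by_asc = sub.sort_values(ascending=True, kind="stable")
        top = by_desc.iloc[:n_sel]
        bottom = by_asc.iloc[:n_sel]
        fast.update(top.index)
        slow.update(bottom.index)
        if (
            occ > n_sel
            and (
                by_desc.iloc[n_sel - 1] == by_desc.iloc[n_sel]
                or by_asc.iloc[n_sel - 1] == by_asc.iloc[n_sel]
            )
        ):
            tied_bins.append(int(b))
    bins = pd.DataFrame(
        {"bin": bin_idx, "base_rank": base_ranks.loc[order], "score": scores.loc[order]}
    )
    return BinSelection(
        fast=frozenset(fast), slow=frozenset(slow), bins=bins, tied_bins=tuple(tied_bins)
    )


def overlap_partition(set_a, set_b, set_c) -> dict:
    """Counts of the seven disjoint regions of a three-set Venn diagram."""
    a, b, c = set(set_a), set(set_b), set(set_c)
    return {
        "A_only": len(a - b - c),
        "B_only": len(b - a - c),
        "C_only": len(c - a - b),
        "AB": len((a & b) - c),
        "AC": len((a & c) - b),
        "BC": len((b & c) - a),
        "ABC": len(a & b & c),
    }
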