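"""Place-ranking of single-copy orthologs with a planted fast lineage.

Simulates gene trees on the eight-taxon wasp phylogeny with Trichogramma's
terminal branch accelerated 2x, extracts root-to-clade-ancestor distances,
tabulates which species carries the longest branch per orthologous group,
and tests the tally against the equal-probability null.
"""

from hymevol import count_tests, tree_rates
from hymevol.phylo import CHALCIDS, null_phylogeny
from hymevol.simulate import SimulationConfig, simulate_gene_trees

config = SimulationConfig(
    seed=42,
    n_orthologs=600,
    species_tree=null_phylogeny(),
    lineage_multipliers={"Trichogramma": 2.0},
)
tree_set, _ = simulate_gene_trees(config)
distances = tree_rates.root_to_anchor_distances(tree_set, config.species_tree)
places = tree_rates.place_table(distances, CHALCIDS)

exact, rendered = tree_rates.expected_place_count(config.n_orthologs, len(CHALCIDS))
first = places.counts[1]
gof = count_tests.chisq_gof(first)

print("1st-place counts per chalcid (longest branch within the ortholog):")
print(first.to_string())
print(f"expected by chance: {exact:.2f} (~{rendered}) per species")
print(f"goodness-of-fit vs uniform null: chi2={gof.statistic:.1f}, p={gof.p:.3g}")
print(
    "-> the accelerated lineage collects far more 1st places than the null\n"
    "   predicts; the small p-value flags genome-wide faster protein evolution."
)

# rank-discrepancy scoring: compare each protein's within-genome rank with
# its base rank (clade-to-order stem), then pick per-bin extremes
ranks = tree_rates.rank_table(distances, CHALCIDS)
scores = ranks["Trichogramma"] - ranks["base_rank"]
selection = tree_rates.bin_and_select(
    scores.astype(float), ranks["base_rank"], bin_size=100, fraction=0.10
)
print(
    f"\nbinned rank-change selection: {len(selection.fast)} 'fast' and "
    f"{len(selection.slow)} 'slow' proteins\n"
    "-> 'fast' proteins rank much higher in the focal genome than their\n"
    "   baseline rate predicts (a positive rank-change score)."
)
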