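"""Gene-family category accounting from an OrthoMCL-style cluster table.

Simulates a cluster table with known composition over the eight wasp
genomes, classifies every annotated gene into the five pan-genome
categories, and counts 'missing' families (absent from exactly one
species).
"""

from hymevol import clusters
from hymevol.simulate import CategoryComposition, SimulationConfig, simulate_cluster_table

table, truth = simulate_cluster_table(
    SimulationConfig(seed=3),
    CategoryComposition(
        n_single_copy_core=20,
        n_variable_copy_core=8,
        n_dispensable=12,
        n_species_specific=3,
        n_singletons=5,
        n_missing=2,
    ),
)
assignment, counts = clusters.classify_genes(table)
print("per-species gene counts by category:")
print(counts.to_string())
print("\nmissing families (sole absentee per family):")
print(clusters.missing_families(table).to_string())

# the 40% rule assigns terms to whole families from member annotations
members = [{"GO:1", "GO:2"}, {"GO:1"}, {"GO:1", "GO:3"}, {"GO:2"}, {"GO:4"}]
kept = clusters.family_terms(members, threshold=0.40)
print(f"\nfamily terms kept at the 40% rule from {len(members)} members: {sorted(kept)}")
print(
    "-> single-copy core families have exactly one gene everywhere; a term\n"
    "   is attached to a family when at least 40% of its members carry it."
)
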