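# hymevol

Comparative molecular-evolution analyses for hymenopteran genomes, built
around the question of whether a focal parasitoid wasp lineage
(*Trichogramma pretiosum*, one of the smallest known insects) shows
genome-wide accelerated protein evolution relative to other chalcidoid
wasps — and around the companion analyses such a comparison needs:
gene-family accounting, gene-body methylation, exon/intron structure and
intraspecific coding divergence.

The package is a library: its public face is the importable API plus the
short narrative scripts in `examples/`. Every analysis stage has a
matching generator in `hymevol.simulate` that produces synthetic inputs
with recorded ground truth, so the whole pipeline runs — and is tested —
without any external download.

## What it computes

**Place ranking of single-copy orthologs** (`hymevol.tree_rates`). For
each orthologous group with one gene tree per ortholog (shared topology,
free branch lengths), extract each species' distance to the clade
ancestor and *place* the species by branch length (1st place = longest
branch = most amino-acid change since the ancestor). Under the
equal-probability null each of *k* species expects *n/k* first places out
of *n* orthologs (1311 orthologs over four chalcids: 327.75 ≈ 328); a
chi-squared goodness-of-fit test flags lineages collecting significantly
more. To find individual proteins, each gets a within-genome rank (1..N
by branch length), a base rank (by the clade-to-order stem, a baseline
rate proxy), and a rank-change score

    score = comparison_rank − base_rank

(base rank 10, median within-clade rank 1000 → +990), with extreme scores
selected inside consecutive base-rank bins of 100 so no baseline-rate
stratum dominates.

**Tajima's relative rate test** (`hymevol.relative_rate`). For aligned
triples (ingroup A, ingroup B, outgroup O), count columns where only A
changed (`mA`) or only B (`mB`); under equal rates
χ² = (mA−mB)²/(mA+mB) with 1 df. Includes a divergence-masking stand-in,
a pooled concatenated test and per-lineage significance summaries with
Benjamini–Hochberg correction.

**Count statistics** (`hymevol.count_tests`): goodness-of-fit, Yates-
corrected 2×2 tests, all-pairs post-hoc comparisons with multiple-testing
adjustment, hypergeometric term enrichment.

**Gene families** (`hymevol.clusters`): OrthoMCL-style groups parsing;
single-copy core / variable-copy core / dispensable / species-specific /
singleton categories; "missing" families (absent from exactly one
species); the ≥40% family-term rule.

**Gene models and methylation** (`hymevol.annotation`,
`hymevol.methylome`): GFF3 gene models, exon/intron totals with
ANOVA + Tukey HSD comparisons, spliced CDS extraction; CpG and GpC
observed/expected per CDS (O/E = N_XY·L / (N_X·N_Y)), read-weighted
gene-body fractional methylation from bisulfite site tables with the
\>0.01 methylated-gene threshold, positional (first/last four exons and
introns) profiles, cross-species conservation labels and log-scale
ortholog methylation correlations.

**Coding divergence** (`hymevol.divergence`): Nei–Gojobori (1986)
synonymous/nonsynonymous site and difference counts with pathway
averaging and Jukes–Cantor correction d = −¾·ln(1 − 4p/3); variant
region/effect classification (silent, missense, nonsense, frameshift);
missense/silent ratios and top-divergence gene selection.

## Worked example

`python examples/place_ranking.py` simulates 600 orthologs on the
eight-taxon wasp phylogeny with the *Trichogramma* terminal branch
accelerated 2×, then runs the place analysis:

```
1st-place counts per chalcid (longest branch within the ortholog):
Ceratosolen      61
Copidosoma       58
Nasonia          49
Trichogramma    432
expected by chance: 150.00 (~150) per species
goodness-of-fit vs uniform null: chi2=707.4, p=5.22e-153
```

The accelerated lineage collects almost three times the 1st places chance
predicts, and the goodness-of-fit p-value rejects the equal-rates null
decisively. The other examples (`relative_rates.py`, `methylation.py`,
`gene_families.py`, `coding_divergence.py`, `intron_exon.py`) each print
one capability's numbers with a line on what they mean.

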