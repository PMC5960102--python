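# Methods

This note documents the models, estimators and numerical choices behind
`hymevol`, and what the synthetic-data generators do and do not emulate.

## Species phylogeny and anchors

All tree analyses assume a single rooted species topology shared by every
per-ortholog gene tree. The default is an eight-taxon hymenopteran tree:
four chalcidoid wasps (*Trichogramma*, *Copidosoma*, *Ceratosolen*,
*Nasonia*) nested inside *Microplitis*, *Apis*, *Orussus*, with the
sawfly *Athalia* as sister to everything else. Two anchors matter: the
**clade root** (MRCA of the four chalcids) and the **order root** (MRCA
of the seven non-sawfly taxa; the sawfly is excluded from order-anchored
comparisons because it subtends the root). Anchors are always resolved
per gene tree as the MRCA of a leaf-name set, never via internal node
labels, so trees from any phylogenetics program are usable unchanged.
Branch lengths on the default tree are plausible amino-acid distances
chosen once; only ratios and ranks matter downstream.

## Place ranking and rank-change scores

Within each orthologous group, clade members are *placed* by their
distance to the clade root (1st = longest). Exact ties are broken by
species-name order and flagged; with continuous branch lengths they only
arise in degenerate inputs. The per-species place counts obey two
marginal identities (each species' counts and each place's counts sum to
the ortholog total) which the implementation asserts.

Rank orientation: within-genome and base ranks run 1..N with rank 1 the
*shortest* branch, so `score = comparison_rank − base_rank` is positive
for proteins relatively faster in the comparison set — reproducing the
worked "+990" sign convention (base rank 10, comparison rank 1000).
Medians over an even number of species are the middle-two mean and may be
half-integer; scores are then rounded half away from zero. Normalised
branch lengths divide the species-to-clade-root distance by the
clade-to-order stem; orthologs with a zero-length stem are excluded with
a warning rather than producing infinities. Bin selection uses
consecutive base-rank bins of 100 (remainder in the final bin); each bin
contributes round(fraction × occupancy), floored at 1, top-score and
bottom-score proteins, with ties at the cut broken by ortholog id and
flagged.

## Relative rate test

For a triple alignment (A, B, O), a column increments `mA` when B and O
share a residue that A lacks, and symmetrically for `mB`; columns with a
gap in any sequence are skipped (a conservative choice — the convention
is not dictated by the test), as are columns where all three differ or
the outgroup is the odd one out. The statistic (mA−mB)²/(mA+mB) is
referred to χ²(1); with mA+mB = 0 the test is undefined and reported so,
never silently p = 1. The masking stand-in removes gap-containing columns
plus columns inside any 10-column window whose mean pairwise identity
falls below 0.5 (both configurable). It is deliberately simple and not
byte-compatible with block-based masking programs; pre-masked alignments
can be supplied instead. Per-gene significance summaries apply
Benjamini–Hochberg at 0.05 by default (raw-α and Bonferroni available) —
a correction is the defensible default even where raw counts are the
convention.

## Count statistics

Goodness-of-fit and 2×2 tests wrap the standard Pearson machinery (the
2×2 applies the Yates continuity correction by default, which is what
reproduces the reference pairwise p-value of 0.6263 on the 353-vs-341
first-place comparison; the uncorrected variant is a flag away).
Post-hoc pairwise comparisons decompose a multi-group test into
success-vs-failure 2×2 tables with joint p-value adjustment
(Benjamini–Hochberg default; Bonferroni and none selectable). Term
enrichment is the hypergeometric upper tail against a caller-supplied
background; the recommended background is every gene with at least one
term annotation.

## Gene families

Categories follow the pan-genome scheme: a family present in every
species is core (single-copy if exactly one gene everywhere, otherwise
variable-copy); present in ≥2 but not all species, dispensable; ≥2 genes
all from one species, species-specific; an annotated gene in no family is
a singleton. The gene universes are explicit inputs, which makes the
singleton definition (all annotated proteins vs proteins entering
clustering) the caller's explicit choice. A family is *missing* for a
species only when that species is the sole absentee. The family-term
rule keeps a term carried by ≥40% of members — the boundary is inclusive
("at least 40%"). Genes from species outside the declared universe are a
hard error, to surface mis-specified universes rather than silently
dropping data.

## Gene models, methylation

Coordinates are GFF3 1-based inclusive throughout; introns are exactly
the gaps between consecutive exons. Genes with several isoforms are
represented by the longest-CDS mRNA so per-gene summaries are
single-valued. Exon/intron length comparisons use one-way ANOVA on raw
totals (callers wanting a log scale transform first) followed by Tukey's
HSD.

Dinucleotide O/E uses (N_XY × L)/(N_X × N_Y) with overlapping windows;
positions holding N are dropped from both L and the base counts and
windows containing N are skipped. Using L rather than L−1 shifts values
by L/(L−1) — negligible for real CDS and fixed across all tests. CpG O/E
is invariant under reverse complement (CpG is its own reverse
complement), and GpC O/E equals the CpG O/E of the C↔G-swapped sequence;
both are property-tested.

Gene-body fractional methylation is read-weighted (Σ methylated / Σ total
over covered CpG sites in the transcribed span, both strands collapsed to
the C position); an unweighted per-site-mean mode exists. A gene is
called methylated iff its fraction strictly exceeds 0.01. A status call
requires at least 3 covered sites by default (configurable): genes below
that report their fraction but a no-data status, since a one-site
"unmethylated" call is not defensible. Positional profiles average
per-feature weighted fractions over the first/last four exons and introns
in transcript orientation; genes with fewer features contribute only to
the slots they have (no imputation). Conservation labels over ≥3 species
partition complete-data orthologs into conserved methylated /
focal-specific gain / focal-specific loss / conserved unmethylated /
other (non-focal changes); orthologs with missing data are excluded and
counted. Cross-species methylation correlation is the product-moment
coefficient on log10(fraction + 1e-4); the floor sits two orders below
the status threshold and is configurable.

## Coding divergence

The Nei–Gojobori (1986) estimator: per-codon synonymous site fractions
from the standard code (changes creating stops count as nonsynonymous),
site counts averaged over the two sequences, observed differences
averaged over all mutational pathways with stop-crossing pathways
excluded (if every pathway crosses a stop, all are used — degenerate but
defined). Jukes–Cantor correction d = −¾ ln(1 − 4p/3) is flagged
undefined at p ≥ ¾ rather than raising. Codons containing ambiguity
codes, gaps or stops are skipped and counted. The estimator choice is a
package default documented as such (raw pN/pS are always reported
alongside). Variant classification uses region precedence coding > UTR >
intron > intergenic across all overlapping models; CDS SNPs are
reclassified by codon recomputation (minus-strand genes through the
reverse complement), CDS indels are frameshifts unless their length is a
multiple of 3. Top-divergence selection (missense per amino-acid site)
includes all genes tied at the cutoff and flags the tie.

## Synthetic-data generators

All generators draw from independent RNG streams seeded by
(config seed, generator name), so outputs are byte-identical under a
fixed seed and adding a generator never perturbs the others.

**Gene trees.** Branch length = species-tree base length × per-ortholog
gamma rate (unit mean, shape 2 by default — protein rates are broadly
dispersed and the distribution is otherwise unconstrained, so gamma is
assumed and exposed) × iid per-branch gamma noise (unit mean, shape 5) ×
a lineage multiplier on the species' terminal branch. The branch-level
noise is essential: without it every gene tree ranks the species
identically and place analyses are degenerate. Setting both shapes to
`None` recovers the exact species-tree lengths. Exchangeability for
null-calibration tests additionally needs equal clade-member root paths,
provided by `null_phylogeny()` (same topology, zero clade-internal
branches, equal clade terminals); on it, equal multipliers make the
1st-place counts exactly uniform in expectation.

**Triple alignments.** A Poisson-style equal-exchangeability protein
model over the 20 residues: per branch, Binomial(L, rate) sites are
substituted to a uniformly chosen different residue, so the expected
unique-substitution count is exactly L × rate. Defaults (L = 500, ingroup
rates 0.03, outgroup 0.06, shared 0.02) give per-gene counts of the order
seen in deep protein comparisons. No among-site rate variation or
exchangeability structure is modelled — the relative rate test consumes
only counts, so these refinements would not change what passing tests
demonstrate.

**Methylome.** 37.4% of genes are methylated (the genome-wide methylated
fraction this kind of bisulfite survey reports), with true fractional
methylation drawn around 0.9 (Beta, concentration 50) versus a constant
0.001 for unmethylated genes — a deliberately well-separated bimodal
configuration. Methylated-class sequence is CpG-depleted by a first-order
chain that thins G-after-C transitions (depletion strength 0.6 → CpG O/E
near 0.4 versus ~1 for the unmethylated class), leaving the GpC control
untouched. Bisulfite counts are Poisson(20) coverage with binomial
methylated reads per site; a non-conversion error ε is available but
defaults to 0. An optional five-prime bias decays per-site fractions
exponentially over transcript-ordered features for positional-profile
tests; it is off by default. Real bisulfite data add alignment error,
strand asymmetries and copy-number artifacts that this generator does not
emulate — passing recovery tests shows the estimator chain is correct at
the stated noise model, not that real libraries are this clean.

**Cluster tables.** Families are composed to order (so classification
must reproduce the requested counts exactly); planted "missing" families
are present in all but one designated species; random dispensable
families are drawn with 2..k−2 species present so they never collide with
the sole-absentee definition.

**Coding pairs.** Sense-codon sequences receive at most one planted
change per codon: synonymous with probability pS × (synonymous sites of
the codon), else nonsynonymous with probability pN × (nonsynonymous
sites), where pS, pN invert the Jukes–Cantor map at the dS/dN targets
(defaults 0.013 and 0.004 — intraspecific-scale synonymous divergence
with strong purifying selection). Changes never create stops, so expected
difference counts match the Nei–Gojobori site denominators exactly and
the estimator recovers the targets within binomial sampling error.

## Problem sizes and tolerances

The test suite runs the closed loops at 60–2000 orthologs, 200–400 genes,
10 pairs × 10⁴ codons — sizes at which every planted effect is detectable
at the stated tolerances while the whole suite stays fast. Parameter
recovery tolerances are pre-registered per test: 2–4 standard errors for
means, ≥95% for methylation-status recovery at 20× coverage, exact
equality for closed-loop ground-truth distances and oracle comparisons
(1e-9). The goodness-of-fit Monte-Carlo oracle compares the asymptotic
Pearson p against the exact multinomial mid-p tail with expected counts
≥ 25 and a 0.02 approximation allowance on top of twice the Monte-Carlo
error — the Pearson p is asymptotic and should not be pretended exact.

## Known limitations

* The masking filter is a stand-in, not a reimplementation of any
  specific masking program.
* The gene-tree generator models rate heterogeneity multiplicatively and
  ignores topological error, alignment uncertainty and among-site rate
  variation.
* Variant classification takes a variant table (CHROM, POS, REF, ALT) as
  given; whole-genome alignment and variant calling are upstream of this
  package.
* Term enrichment treats annotations as flat sets; no ontology-graph
  propagation is performed.
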