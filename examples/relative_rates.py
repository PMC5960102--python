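"""Tajima's relative rate test on simulated triple protein alignments.

Simulates (ingroup A, ingroup B, outgroup) alignments in which lineage A
carries twice lineage B's substitution rate, runs the per-gene relative
rate test and the pooled concatenated test, and summarises significant
genes per lineage after false-discovery-rate correction.
"""

from hymevol import relative_rate as rr
from hymevol.simulate import SimulationConfig, simulate_triple_alignments

config = SimulationConfig(seed=7, n_orthologs=300, alignment_length=400)
alignments, _ = simulate_triple_alignments(config, rates=(0.06, 0.03, 0.05, 0.01))

results = [rr.tajima_test_alignment(a) for a in alignments]
summary = rr.rate_test_summary(results, alpha=0.05, correction="fdr_bh")
concat = rr.concatenated_test(alignments)

print(f"per-gene tests: {summary.n_tested} genes, "
      f"{summary.n_significant} significant after BH correction")
print(f"  faster in lineage A: {summary.n_faster_a}, "
      f"faster in lineage B: {summary.n_faster_b}")
print(f"concatenated test: mA={concat.mA}, mB={concat.mB}, "
      f"chi2={concat.chi2:.1f}, p={concat.p:.3g}")
print(
    "-> mA counts alignment columns where only lineage A changed (B and the\n"
    "   outgroup agree). With A simulated 2x faster, significant genes point\n"
    "   overwhelmingly to A, and pooling all genes gives a decisive test."
)
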