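"""Per-gene exon/intron totals and the cross-species length comparison.

Builds gene models from a simulated annotation, totals exon and intron
lengths per gene, and compares species groups with one-way ANOVA plus
Tukey's honest-significant-difference test (here: three pseudo-species,
one with systematically shorter introns).
"""

import numpy as np

from hymevol import annotation as an
from hymevol.simulate import SimulationConfig, simulate_methylome

data = simulate_methylome(SimulationConfig(seed=9, n_genes=240))
totals = np.array([an.exon_intron_totals(m) for m in data.models])
exon_bp, intron_bp = totals[:, 0], totals[:, 1]
print(f"{len(data.models)} genes: mean exon total {exon_bp.mean():.0f} bp, "
      f"mean intron total {intron_bp.mean():.0f} bp per gene")

# three pseudo-species: the third gets introns shrunk by 40%
groups = {
    "speciesA": intron_bp[:80].astype(float),
    "speciesB": intron_bp[80:160].astype(float),
    "speciesC": intron_bp[160:].astype(float) * 0.6,
}
res = an.length_comparison(groups)
print("\nper-species mean intron totals:")
print(res.means.round(0).to_string())
print(f"one-way ANOVA: F={res.f_statistic:.1f}, p={res.p:.3g}")
print(res.tukey.to_string(index=False))
print(
    "-> the ANOVA detects the planted intron-length reduction and the Tukey\n"
    "   table shows which species pairs differ."
)
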