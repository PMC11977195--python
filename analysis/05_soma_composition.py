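#!/usr/bin/env python
"""Cell-composition simulation of the MR apparent soma radius.

Builds the baseline grey-matter voxel (literature cell densities, Gaussian
radius distributions), couples cell counts to age through the default
fractional slopes (oligodendrocyte-dominant increase, glial/endothelial
decline), and sweeps ages 8-19 y, reporting the Monte-Carlo and analytic
apparent radius and the endpoint percent change.
"""

from cortexdev import io as cio
from cortexdev import soma_sim as ss

OUT = "results/analysis"
SEED = 1

pops = ss.default_populations()
base = ss.analytic_apparent_radius(pops)
print("baseline voxel composition:")
for p in pops:
    print(f"  {p.name:>15s}: {p.count:>8.0f} /mm^3, radius {p.radius_mean} +- {p.radius_sd} um")
print(f"baseline apparent soma radius (analytic): {base.r_app:.3f} um")
print("(moment weighting pulls the estimate toward the largest cells)")

sweep, pct = ss.age_sweep(
    pops, ss.DEFAULT_SLOPES, ages=list(range(8, 20)), n_samples=100_000, seed=SEED
)
cio.write_table(sweep, f"{OUT}/soma_sweep.tsv", header_comment=f"seed={SEED}")
print(f"\nage sweep 8->19 y with slopes {ss.DEFAULT_SLOPES}:")
print(sweep.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print(f"\napparent-radius percent change 8->19 y: {pct:+.2f}% "
      "(direction set by the oligodendrocyte-dominant composition shift; the "
      "magnitude scales with the configured slope calibration)")
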