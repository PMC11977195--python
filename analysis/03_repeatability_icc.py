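#!/usr/bin/env python
"""Test-retest repeatability of the simulated microstructure metrics.

Computes ICC(2,1) — single measure, two-way random effects, absolute
agreement — on the 6x5 repeatability table, and summarizes the estimator's
small-sample behaviour over 200 replicate tables at the generating
variance-component ratio of 0.97.
"""

import numpy as np

from cortexdev import io as cio
from cortexdev import microstructure_stats as ms
from cortexdev import synthetic_data as sd

OUT = "results/analysis"
rep = cio.read_table(f"{OUT}/repeatability.tsv")

r = ms.icc_absolute_agreement(rep, "f_neurite")
print(f"single-table ICC(2,1) for f_neurite: {r.icc:.3f} (n={r.n}, k={r.k})")

vals = []
for s in range(200):
    t = sd.generate_repeatability(
        sd.RepeatabilitySpec(
            sigma_subject=np.sqrt(0.97), sigma_session=np.sqrt(0.015),
            sigma_error=np.sqrt(0.015), seed=s + 1,
        )
    )
    vals.append(ms.icc_absolute_agreement(t, "f_neurite").icc)
vals = np.array(vals)
cio.write_table(
    __import__("pandas").DataFrame({"replicate": np.arange(1, 201), "icc": vals}),
    f"{OUT}/icc_replicates.tsv",
)
print(f"200 replicates at true ratio 0.97: mean {vals.mean():.3f}, SD {vals.std(ddof=1):.3f}")
print("note: the ICC(2,1) estimator is downward-biased by ~0.016 at a 6x5 grid"
      " (Jensen bias of the mean-square ratio); see docs/methods.md")
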