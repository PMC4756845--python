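"""Duplicate-pair concordance before and after correction.

Raw beta correlation between any two blood samples is ~0.99 because the
bimodal methylation pattern is shared genome-wide, so the evaluation
uses mean-centered correlation (expected 0 for unrelated samples) and
the mean absolute beta difference per pair.
"""

import numpy as np
import pandas as pd

from enmix import (
    SimulationSpec,
    compare_methods,
    compute_beta,
    enmix_correct,
    simulate_duplicates,
)

spec = SimulationSpec(seed=11, n_probes=8000)
x, design, _ = simulate_duplicates(spec, n_pairs=8)

betas = lambda z: pd.DataFrame(
    compute_beta(z.M.to_numpy(float), z.U.to_numpy(float)),
    index=z.probe_ids, columns=z.samples)

raw = betas(x)
a, b = design.pairs[0]
print(f"raw Pearson correlation of pair {a}/{b}: "
      f"{np.corrcoef(raw[a], raw[b])[0, 1]:.4f} (near-ceiling, uninformative)")

corrected, _ = enmix_correct(x, x.manifest, "oob")
report = compare_methods(raw, {"enmix_oob": betas(corrected)}, duplicates=design)
print("\n", report.round(4))
print(
    "\nMean-centered correlation rises and the mean absolute beta\n"
    "difference (percentage points) falls after correction; the one-sided\n"
    "paired t-test p-values compare each method against raw."
)
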