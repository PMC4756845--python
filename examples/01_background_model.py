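"""The observed-intensity model and the conditional-mean correction.

Builds one convolution model (exponential + truncated-normal signal
mixture plus truncated-normal background), checks that its closed-form
density is a proper distribution, and shows what the correction
E(X|S=s) does to a few observed intensities.
"""

import numpy as np
from scipy.integrate import quad

from enmix import (
    ConvolutionModel,
    SignalMixtureParams,
    TruncNormalParams,
    component_posterior,
    conditional_signal_mean,
    observed_density,
)

# half the probes' signals decay from zero (dim allele, Exp with mean
# 2500), half cluster around 9000 (bright allele); background sits at
# 600 +/- 90
model = ConvolutionModel(
    signal=SignalMixtureParams(p1=0.5, lam=1 / 2500, normal=TruncNormalParams(9000, 2000)),
    background=TruncNormalParams(600, 90),
)

total = quad(lambda s: observed_density(s, model), 1e-9, 3e5, limit=500)[0]
print(f"observed density integrates to {total:.8f} (should be 1)")

print(f"\n{'observed s':>12} {'P(exp comp|s)':>14} {'E(X|S=s)':>10} {'shrink':>8}")
for s in [300.0, 700.0, 1500.0, 5000.0, 9000.0, 15000.0, 65535.0]:
    w = component_posterior(s, model)
    e = conditional_signal_mean(s, model)
    print(f"{s:12.0f} {w:14.3f} {e:10.1f} {s - e:8.1f}")

print(
    "\nDim intensities (s near the background) are shrunk almost to zero;\n"
    "bright intensities lose roughly the mean background (~600 units).\n"
    "The correction is smooth, strictly positive and order-preserving —\n"
    "no intensity is ever truncated."
)
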