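# enmix

Model-based background correction for Illumina Infinium methylation
arrays (450K-style), with the surrounding preprocessing, QC and
evaluation tooling, and a ground-truth simulator.

## The problem

An Infinium array reports two fluorescence intensities per CpG — the
methylated (M) and unmethylated (U) allele — and the methylation level
is estimated as `beta = M / (M + U + 100)`.  Both intensities carry
optical/chemical background on top of the true signal.  Simple fixes
subtract a constant (e.g. the 5th percentile of the negative controls)
and clip at zero, which truncates dim probes wholesale and still leaves
the betas biased toward 0.5; the bias is worst exactly at the fully
methylated/unmethylated extremes that dominate real methylomes, and it
differs between the two assay chemistries (Infinium I vs II).

## The model

Each observed intensity is modelled as `S = X + Y` where

* `X` — the true signal — follows a two-component mixture
  `p1 · Exp(λ) + p2 · N₊(ν, τ²)` (exponential for the essentially-absent
  allele, zero-truncated normal for the bright allele; `p1 + p2 = 1`);
* `Y` — the background — follows an independent zero-truncated normal
  `N₊(μ, σ²)`.

The array is split into six parts per sample (Infinium I red M/U,
Infinium I green M/U, Infinium II green M, Infinium II red U) and the
mixture is fitted to each part by EM.  The background `(μ, σ)` comes
from one of three routes:

| route | source | granularity |
|-------|--------|-------------|
| `neg` | 613 negative-control probes | per colour channel |
| `oob` | out-of-band Infinium I intensities (~10⁵ values) | per colour channel |
| `est` | joint maximum likelihood on pooled M+U data | per probe class × channel |

Every intensity is then replaced by its conditional expected signal
`E(X | S = s)`, evaluated in closed form via normal-CDF differences
(erfcx-stable in both tails).  The correction is strictly positive,
strictly increasing in `s`, and never truncates — the key contrast with
subtraction baselines (`q5`, `lumi1`, `lumi2`, provided here for
benchmarking).  Dye-bias scaling from the 186 non-polymorphic controls
and four-stratum quantile normalisation (M/U × Infinium I/II) compose
with it in the fixed order correction → dye bias → quantile.

## Worked example

```python
import numpy as np
from enmix import SimulationSpec, simulate_array, enmix_correct, compute_beta

spec = SimulationSpec(seed=7, n_probes=8000, n_samples=3)
x, truth = simulate_array(spec)                    # known latent signals
corrected, diag = enmix_correct(x, x.manifest, method="oob")

for name, raw, cor, t in [("M", x.M, corrected.M, truth.X_M),
                          ("U", x.U, corrected.U, truth.X_U)]:
    print(name, np.abs(raw.to_numpy() - t.to_numpy()).mean(),
          np.abs(cor.to_numpy() - t.to_numpy()).mean())
```

prints (see `examples/02_simulate_and_correct.py` for the full script):

```
simulated 8000 probes x 3 samples (28% Infinium I)
M: mean |intensity - true signal|  raw   891.2  corrected   258.9
U: mean |intensity - true signal|  raw   658.6  corrected   183.0
beta: mean |beta - true beta|        raw 0.0595  corrected 0.0184
```

i.e. the corrected intensities sit ~3× closer to the latent true
signals, and the betas ~3× closer to the true methylation fractions.
The other scripts in `examples/` demonstrate the probability model
itself, duplicate-pair concordance (mean-centered correlation and mean
absolute beta difference with paired t-tests), titration-standard
accuracy (signed per-level median deviation), and the composed
pipeline with QC filters and the multimodality screen.

A thin CLI mirrors the library surface for shell use:
`enmix simulate | correct | normalize | qc | evaluate | pipeline`
(all I/O is delimited text; `--help` on any subcommand).

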