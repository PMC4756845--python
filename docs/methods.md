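# Methods

## Observed-intensity model

For one sample and one of the six intensity parts (design type ×
channel × allele), an observed intensity is

    S = X + Y,
    X ~ p1 · Exp(λ) + (1 − p1) · N₊(ν, τ²),
    Y ~ N₊(μ, σ²),

with `N₊` a normal left-truncated at zero.  The exponential component
carries the probes whose interrogated allele is essentially absent
(density decaying from zero with a heavy right tail); the truncated
normal carries the bright present-allele probes.  Because a CpG's
methylation state swaps which of M and U is the dim allele, the same
mixture describes every part, with `p1` equal to the fraction of
dim-allele measurements in that part.

### The correction E(X | S = s)

Conditional on the component, the joint density of `(X, S)` restricts a
normal kernel in `x` to the interval `(0, s)` (both `X ≥ 0` and
`Y = s − X ≥ 0` must hold):

* exponential component — completing the square in
  `e^{−λx} · φ((s−x−μ)/σ)` gives a normal with location
  `m₁ = s − μ − σ²λ` and scale `σ`, truncated to `(0, s)`;
* normal component — the Gaussian product identity gives the
  precision-weighted location
  `m₂ = (ν/τ² + (s−μ)/σ²) / (1/τ² + 1/σ²)` and variance
  `(1/τ² + 1/σ²)^{−1}`, truncated to `(0, s)`.

`E(X|S=s)` is the posterior-weighted average of the two truncated-normal
interval means, the posterior weight being `p1·f₁(s) / f_S(s)` with the
component convolution densities `f₁, f₂` in closed form via normal-CDF
differences.  In the limit `p1 = 1` with negligible truncation this is
exactly the classic normal-exponential ("normexp") correction; the
doubly-truncated form additionally guarantees `0 < E(X|S=s) < s` for
every `s > 0`.

The derivation is forced by the model; nevertheless an adaptive-
quadrature oracle (integrand restricted to the background window and
rescaled by its log-peak; absolute tolerance 1e−14 after rescaling,
four orders tighter than any assertion) is the source of truth in the
test suite, guarding the algebra at 200 random (model, s) pairs to
1e−6 relative.

### Numerical strategy

All tail quantities go through `erfcx` or `log_ndtr`:

* `log(Φ(b) − Φ(a))` is evaluated in whichever tail keeps the CDFs away
  from 1 (the straddling case uses the direct difference, exact to
  ~1e−17 absolute);
* truncated-normal interval means use the scaled-complementary-error
  representation in either tail, `expm1` for the near-cancelling
  difference of exponentials, and a midpoint rule for intervals
  narrower than 1e−8 standard deviations;
* component posteriors are formed from log-density differences, so no
  intensity up to (and far beyond) the 2¹⁶ scanner ceiling produces a
  NaN or Inf.

## Parameter estimation

### Background: negative controls and out-of-band intensities

Both channel-level routes use median/MAD (scale factor 1.4826) followed
by one truncation-aware refinement: the median and MAD of
`N₊(m₀, s₀²)` are computed numerically and the map is inverted once,
removing the first-order bias when the background sits close to zero.
The refinement is a no-op in the usual regime `μ ≫ σ`.  σ is floored at
1 intensity unit (the scanner quantisation scale); fewer than 20 values
or a zero-spread sample is refused.  The out-of-band route applies the
same estimator to the ~10⁵ readings of type I probes on their unused
channel (a red-assigned probe's unused reading is a *green*
measurement, and vice versa), which makes it markedly more precise than
the 613 negative controls — the test suite checks this as an RMSE
comparison over 100 replicates.

### Signal mixture and the est route

Given a background, `(p1, λ, ν, τ)` is fitted by EM over the latent
component label.  The E-step is the component posterior; the M-step
updates `p1` in closed form and improves `λ` (bounded 1-D search in
log-λ) and `(ν, log τ)` (Nelder–Mead) on the expected complete-data
log-likelihood — a generalised EM: every block starts from the current
value and is accepted only if it improves, so the observed
log-likelihood is non-decreasing (asserted to 1e−8 on every run).
Convergence: relative log-likelihood change below 1e−6, cap 1000
iterations.  Initialisation is deterministic and scale-aware
(`p1 = 0.5`, `λ = 1/median`, `ν` = 75th percentile, `τ` = scaled MAD of
the upper half); any subsampling (default cap 5·10⁴ points) uses a
caller-provided seed, so a pipeline run is bit-reproducible.

The `est` route frees `(μ, σ)` as an additional M-step block on the
pooled M+U data of one probe class × channel (minimum 5000 values).
It is the only route that resolves the systematically higher
Infinium II background, and the route of choice when control data were
never deposited.

**Identifiability guards.**  The likelihood alone cannot distinguish a
far-left truncated normal from an exponential (its restriction to the
positive axis is a pure decay), so three constraints keep the
components meaningful: `ν ≥ τ/2` always (the bright component must be a
peaked bump, not a decay — the constraint does not bind the realistic
parameter ranges); `ν ≥ μ + 2σ` and `−2σ ≤ μ ≤ median(s)` under a free
background (no signal/background swap, no background-as-exponential).
After EM, a BIC-style test collapses the fit to a single component when
that component alone explains the data within the parameter-count
penalty (3·log n / 2 for dropping the normal, log n for dropping the
exponential): on pure-exponential data the two-component MLE is always
marginally better in raw likelihood, so without this test `p1` would
converge to an arbitrary interior split.

**Known limitation.**  When `p1` is small and the bright normal is
broad (`ν/τ` near its guard), the split between σ and τ — and between
μ and ν — is weakly identified and the free-background fit can land a
corner model on the wrong ridge.  Median parameter-recovery error over
25 random realistic models at n = 5·10⁴ is ~1% for μ, ν, λ and ~2–5%
for σ, τ, p1, but individual worst cases reach tens of percent; the
channel-level routes (which fix the background from control data) do
not share this failure mode.

## Preprocessing pipeline

* **Correction** is per sample and per part; for `neg`/`oob` one
  background per channel is shared by that channel's parts, for `est`
  backgrounds are per class × channel.  Corrected intensities keep the
  within-part ordering of the raw values and are strictly positive.
* **Baselines** `q5` (5th percentile of negative controls, linear
  interpolation), `lumi1` (their median) and `lumi2` (the 100-bin
  histogram mode of the channel's methylated intensities) subtract a
  per-channel constant and floor at zero; the induced truncated
  fraction is reported in the diagnostics.
* **Dye bias**: with 20%-trimmed means R̄, Ḡ of the red-/green-target
  non-polymorphic controls, red intensities scale by (R̄+Ḡ)/(2R̄) and
  green by (R̄+Ḡ)/(2Ḡ), meeting at the common mean.  The published
  reference method for this step is not specified in detail anywhere
  accessible; this symmetric control-anchored scaling is the simplest
  member of the family and is isolated behind one function.
* **Quantile normalisation** runs independently in four strata
  (M/U × Infinium I/II) so it never mixes chemistries or alleles; ties
  map to the average of the tied quantiles.  A single sample returns
  unchanged with a warning.
* Steps compose only in the order correction → dye bias → quantile;
  beta values use the standard offset (default 100) regardless of
  which steps ran.  BMIQ-style beta-scale methods are a hook
  (`PipelineConfig.beta_hook`), not an implementation.

## QC and summaries

* **Detection p-value**: `p = (#{control sums ≥ M+U} + 1)/(n+1)`
  against the empirical distribution of summed negative-control
  intensities matched to the chemistry — a type I probe sums two values
  from its assigned channel (implemented as 2× each control value), a
  type II probe one green plus one red value paired in table order.
  The +1 convention avoids exact zeros; the statistic is monotone
  non-increasing in M+U.  The channel-combination convention (sum, not
  max) is a documented package choice.
* **Exclusion mask**: a measurement is dropped iff a bead count is
  strictly below 3 or the detection p-value strictly above 0.05
  (strict inequalities; boundary values survive).
* **Multimodality screen (`nmode`)**: local maxima of a 20-bin
  histogram on [0,1]; a peak needs >5% of samples, and two peaks are
  distinct only if the valley between them drops below 50% of the
  smaller peak.  Needs ≥20 samples.

## Evaluation metrics

Mean-centered correlation subtracts each CpG's across-sample mean
before correlating a duplicate pair — raw beta correlation is ~0.99
even between unrelated samples, so centering is what makes the metric
informative.  It requires ≥3 samples: with exactly the pair present,
centering maps the columns onto mirror images and r ≡ −1.  The mean
absolute beta difference is reported in percentage points.  Titration
deviation is the signed per-level median of (beta − expected level);
the sign matters because background produces positive bias at the
unmethylated extreme and negative at the methylated extreme, and the
report also carries the mean |deviation| as an overall figure.
Method comparisons use one-sided paired t-tests against raw (NaN when
the methods are identical or fewer than two pairs exist).  Missing
betas are handled pairwise-complete, since QC masking creates holes.

## Simulator

The generator emits everything the estimation routes consume: M/U
matrices, out-of-band readings for exactly the type I probes (drawn
from the opposite channel's background), 613 negative controls and
186 non-polymorphic controls per sample, optional bead counts, and a
ground-truth sidecar for which `observed = X + Y` reconstructs the
emitted values exactly.

Structure and defaults (all overridable on `SimulationSpec`; a seed is
mandatory and every run is bit-reproducible):

* 28% Infinium I (channels split evenly), 72% Infinium II; per-CpG
  hypo/hyper state (50/50) shared by all samples, which produces the
  characteristic bimodal beta distribution and the near-ceiling raw
  correlation between unrelated samples.
* Signal scales: dim allele Exp(mean 500), bright allele
  N₊(10⁴, 2000²) — a dim:bright ratio giving hypomethylated betas
  around 0.05, with the dim allele at the background scale, which is
  precisely the regime in which background correction matters.
* Backgrounds: red N₊(500, 80²), green N₊(600, 90²) for type I;
  type II locations 1.5× higher.  Technical layers per sample:
  scanner gain (lognormal sd 0.10) on every measurement and a
  background-level factor (lognormal sd 0.25) per channel on the noise
  layer and its control/out-of-band draws, emulating chip-to-chip
  variation.
* Duplicates: a CpG-anchored baseline signal drawn once, a per-subject
  biological factor (lognormal sd 0.15) shared within a pair, and
  member-level technical noise (lognormal sd 0.05); backgrounds,
  controls and out-of-band values independent per member.  The noise
  composition was set once so the *raw* metrics land in the regime the
  evaluation designs show on real arrays (raw Pearson ≈ 0.99,
  mean-centered correlation ≈ 0.4–0.5, mean absolute difference
  ≈ 2 percentage points) and then frozen.
* Titration: levels 0/5/10/20/40/50/60/80/100% with replicate counts
  (10,3,2,3,3,2,3,3,10) — 39 samples; M-signal ∝ level, U-signal ∝
  (1 − level), full-scale intensities from the bright component, plus
  a small exponential non-specific floor (mean 100 units) so the
  extreme levels are not exactly background-only.

What the simulator does *not* model: probe-specific affinities,
bead-level replicates, spatial chip artifacts, bisulfite-conversion
chemistry, SNP-driven multimodality.  Passing end-to-end tests
therefore show that the estimation and correction machinery recovers
the model's own generative process under realistic technical
variation — not that real-array gains will match these magnitudes.

## Problem sizes in the shipped studies

The test suite runs the duplicate study at 20 pairs × 10⁴ probes, the
titration study at the full 39-sample design × 8000 probes (the
smallest array clearing the ≥1000-values-per-part fit precondition),
and parameter recovery at 25 models × 5·10⁴ points; the acceptance
script uses slightly smaller sizes (20 pairs × 8000 probes, 8 recovery
models at 3·10⁴ points) as its standard configuration.  These sizes
are the package's chosen defaults for routine verification; all scale
linearly if larger studies are wanted.
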