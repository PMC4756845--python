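"""The preprocessing pipeline: model-based background correction,
comparator subtraction baselines, dye-bias scaling and stratified
quantile normalisation.

The central step, :func:`enmix_correct`, fits the exponential-normal
mixture convolution model to each of the six intensity parts of every
sample and replaces each observed intensity by its conditional expected
signal E(X|S=s) — a smooth, strictly positive, order-preserving
adjustment.  Background parameters come from one of three routes:

* ``neg``  — negative-control probes, one (mu, sigma) per colour channel;
* ``oob``  — out-of-band type I intensities, per channel (larger sample,
  usually the best choice when oob data are available);
* ``est``  — joint maximum likelihood on the pooled M+U data, per
  probe class x channel (the only route that resolves the higher
  Infinium II background, and the only one possible when control data
  were not deposited).

Steps compose in the fixed order correction -> dye bias -> quantile
normalisation ("ENmix", "ENmixD", "ENmixDQ" in the field's shorthand).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.stats import rankdata, trim_mean

from .array_data import (
    PART_CHANNEL,
    PART_NAMES,
    BetaMatrix,
    IntensitySet,
    ProbeManifest,
    compute_beta,
    split_six_parts,
)
from .core_model import ConvolutionModel, conditional_signal_mean
from .estimation import (
    BackgroundParams,
    estimate_background_est,
    estimate_background_neg,
    estimate_background_oob,
    fit_signal_mixture,
)

__all__ = [
    "PipelineConfig",
    "enmix_correct",
    "baseline_correct",
    "dye_bias_correct",
    "quantile_normalize",
    "run_pipeline",
]

_STEP_ORDER = ("enmix", "dye_bias", "quantile")

#: probe class of each part, for the est route's class-resolved backgrounds
_PART_CLASS = {name: ("typeI" if name.startswith("I-") else "typeII") for name in PART_NAMES}

_MIN_INTENSITY = 1e-3  # floor applied before correction; scanner floor is >= 0


@dataclass
class PipelineConfig:
    """Configuration of :func:`run_pipeline`.

    ``steps`` is an ordered subset of ("enmix", "dye_bias", "quantile");
    the canonical order is enforced.  ``bmiq`` and ``combat`` hook points
    accept user-supplied callables applied to the beta matrix / passed the
    final betas, since those published methods are out of scope here.
    """

    background_method: str = "oob"
    steps: tuple = ("enmix", "dye_bias", "quantile")
    beta_offset: float = 100.0
    subsample_seed: int = 0
    max_fit_points: int = 50_000
    beta_hook: object = None  # e.g. a BMIQ implementation, beta -> beta

    def __post_init__(self) -> None:
        if self.background_method not in ("neg", "oob", "est"):
            raise ValueError(f"unknown background method {self.background_method!r}")
        unknown = [s for s in self.steps if s not in _STEP_ORDER]
        if unknown:
            raise ValueError(f"unknown steps: {unknown}")
        order = [_STEP_ORDER.index(s) for s in self.steps]
        if order != sorted(order) or len(set(order)) != len(order):
            raise ValueError(f"steps must respect the order {_STEP_ORDER}")
        if self.beta_offset < 0:
            raise ValueError("beta_offset must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "steps" in raw:
            raw["steps"] = tuple(raw["steps"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {
            "background_method": self.background_method,
            "steps": list(self.steps),
            "beta_offset": self.beta_offset,
            "subsample_seed": self.subsample_seed,
            "max_fit_points": self.max_fit_points,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)


# ---------------------------------------------------------------------------
# model-based correction
# ---------------------------------------------------------------------------

def _channel_backgrounds(x: IntensitySet, manifest: ProbeManifest, sample, method: str):
    """Per-channel (neg/oob) background parameters for one sample."""
    if method == "neg":
        return {
            ch: estimate_background_neg(x.negative_controls(sample, ch), ch)
            for ch in ("red", "green")
        }
    if x.oob_M is None or x.oob_U is None:
        raise ValueError("method 'oob' needs out-of-band intensity matrices")
    i_red = manifest.ids_of("I", "red")
    i_green = manifest.ids_of("I", "green")
    # a red-assigned probe's unused reading is a green-channel measurement
    green_sample = np.concatenate([
        x.oob_M.loc[i_red, sample].to_numpy(float),
        x.oob_U.loc[i_red, sample].to_numpy(float),
    ])
    red_sample = np.concatenate([
        x.oob_M.loc[i_green, sample].to_numpy(float),
        x.oob_U.loc[i_green, sample].to_numpy(float),
    ])
    return {
        "red": estimate_background_oob(red_sample, "red"),
        "green": estimate_background_oob(green_sample, "green"),
    }


def _est_backgrounds(parts, sample, seed, max_points):
    """Per probe-class x channel backgrounds from pooled M+U data."""
    pools = {
        ("typeI", "red"): ["I-red-M", "I-red-U"],
        ("typeI", "green"): ["I-green-M", "I-green-U"],
        ("typeII", "green"): ["II-green-M"],
        ("typeII", "red"): ["II-red-U"],
    }
    out = {}
    for (cls, ch), names in pools.items():
        pooled = np.concatenate(
            [parts[n][sample].to_numpy(float) for n in names])
        out[(cls, ch)] = estimate_background_est(
            pooled, ch, cls, seed=seed, max_points=max_points)
    return out


def enmix_correct(
    x: IntensitySet,
    manifest: ProbeManifest,
    method: str = "oob",
    *,
    seed: int = 0,
    max_fit_points: int = 50_000,
) -> tuple[IntensitySet, dict]:
    """Replace every M/U intensity by its conditional expected signal.

    For each sample and each of the six parts: estimate the background by
    the chosen route, fit the signal mixture by EM, then map every
    intensity s to E(X|S=s).  Corrected intensities are strictly positive
    and keep the within-part ordering of the raw values.

    Returns the corrected set and a JSON-serialisable diagnostics dict
    (fitted parameters and convergence info per sample and part).
    """
    if method not in ("neg", "oob", "est"):
        raise ValueError(f"unknown background method {method!r}")
    parts = split_six_parts(x, manifest).parts
    out = x.copy()
    diagnostics: dict = {"method": method, "samples": {}}
    for sample in x.samples:
        if method in ("neg", "oob"):
            chan_bg = _channel_backgrounds(x, manifest, sample, method)
        else:
            class_bg = _est_backgrounds(parts, sample, seed, max_fit_points)
        sample_diag = {}
        for name in PART_NAMES:
            frame = parts[name]
            if frame.empty:
                continue
            values = frame[sample].to_numpy(dtype=float)
            bg: BackgroundParams = (
                chan_bg[PART_CHANNEL[name]]
                if method in ("neg", "oob")
                else class_bg[(_PART_CLASS[name], PART_CHANNEL[name])]
            )
            try:
                signal, fit_diag = fit_signal_mixture(
                    values, bg, seed=seed, max_points=max_fit_points)
            except ValueError as err:
                raise ValueError(f"part {name!r}, sample {sample!r}: {err}") from err
            model = ConvolutionModel(signal, bg.as_truncnormal())
            corrected = conditional_signal_mean(
                np.maximum(values, _MIN_INTENSITY), model)
            target = out.M if name.endswith("-M") else out.U
            target.loc[frame.index, sample] = corrected
            sample_diag[name] = {
                "background": {"mu": bg.mu, "sigma": bg.sigma,
                               "channel": bg.channel, "method": bg.method,
                               "probe_class": bg.probe_class},
                "signal": {"p1": signal.p1, "lam": signal.lam,
                           "nu": signal.nu, "tau": signal.tau},
                "n_iter": fit_diag.n_iter,
                "converged": fit_diag.converged,
                "loglik": fit_diag.loglik_trace[-1],
                "flags": fit_diag.flags,
            }
        diagnostics["samples"][sample] = sample_diag
    diagnostics["truncated_fraction"] = 0.0  # E(X|S=s) never truncates
    return out, diagnostics


# ---------------------------------------------------------------------------
# comparator baselines (one-line subtraction rules)
# ---------------------------------------------------------------------------

def _channel_masks(manifest: ProbeManifest):
    """Row masks of red- and green-channel measurements for M and U."""
    t = manifest.table
    is_two = (t["design_type"] == "II").to_numpy()
    chan = t["channel"].to_numpy(dtype=object)
    return {
        ("M", "red"): (~is_two) & (chan == "red"),
        ("M", "green"): ((~is_two) & (chan == "green")) | is_two,
        ("U", "red"): ((~is_two) & (chan == "red")) | is_two,
        ("U", "green"): (~is_two) & (chan == "green"),
    }


def _mode_estimate(values: np.ndarray, n_bins: int = 100) -> float:
    counts, edges = np.histogram(values, bins=n_bins)
    k = int(np.argmax(counts))
    return 0.5 * (edges[k] + edges[k + 1])


def baseline_correct(
    x: IntensitySet,
    manifest: ProbeManifest,
    method: str,
) -> tuple[IntensitySet, dict]:
    """Constant-subtraction baselines: ``q5``, ``lumi1`` or ``lumi2``.

    q5 subtracts the 5th percentile (linear-interpolation convention) of
    the negative controls per channel, lumi1 their median, lumi2 the
    histogram mode of the methylated intensities per channel.  Results
    are floored at zero; the induced truncated fraction is reported in
    the diagnostics — this is exactly the artifact the model-based
    correction avoids.
    """
    if method not in ("q5", "lumi1", "lumi2"):
        raise ValueError(f"unknown baseline method {method!r}")
    masks = _channel_masks(manifest)
    out = x.copy()
    diag = {"method": method, "truncated_fraction": {}, "offsets": {}}
    for sample in x.samples:
        offsets = {}
        for ch in ("red", "green"):
            if method in ("q5", "lumi1"):
                ctrl = x.negative_controls(sample, ch)
                offsets[ch] = float(
                    np.percentile(ctrl, 5) if method == "q5" else np.median(ctrl))
            else:
                m_vals = x.M.loc[masks[("M", ch)], sample].to_numpy(float)
                offsets[ch] = _mode_estimate(m_vals)
        n_trunc = n_tot = 0
        for which, target in (("M", out.M), ("U", out.U)):
            for ch in ("red", "green"):
                mask = masks[(which, ch)]
                vals = target.loc[mask, sample].to_numpy(float) - offsets[ch]
                n_trunc += int((vals < 0).sum())
                n_tot += vals.size
                target.loc[mask, sample] = np.maximum(vals, 0.0)
        diag["offsets"][sample] = offsets
        diag["truncated_fraction"][sample] = n_trunc / n_tot
    return out, diag


# ---------------------------------------------------------------------------
# dye bias and quantile normalisation
# ---------------------------------------------------------------------------

def dye_bias_correct(x: IntensitySet, manifest: ProbeManifest) -> IntensitySet:
    """Equalise red/green intensity scales using non-polymorphic controls.

    Per sample, with robust (20%-trimmed) means Rbar and Gbar of the red-
    and green-target non-polymorphic controls, red intensities are scaled
    by (Rbar+Gbar)/(2*Rbar) and green by (Rbar+Gbar)/(2*Gbar), so both
    channels meet at the common mean.  Out-of-band and control values are
    scaled along with their measurement channel.
    """
    masks = _channel_masks(manifest)
    t1 = manifest.table.set_index("probe_id").loc[manifest.ids_of("I")]
    oob_chan = t1["channel"].to_numpy(dtype=object)  # assigned channel
    out = x.copy()
    for sample in x.samples:
        rbar = float(trim_mean(x.nonpolymorphic_controls(sample, "red"), 0.2))
        gbar = float(trim_mean(x.nonpolymorphic_controls(sample, "green"), 0.2))
        if rbar <= 0 or gbar <= 0:
            raise ValueError(f"non-positive control mean for sample {sample!r}")
        f_red = (rbar + gbar) / (2.0 * rbar)
        f_green = (rbar + gbar) / (2.0 * gbar)
        factor = {"red": f_red, "green": f_green}
        for which, target in (("M", out.M), ("U", out.U)):
            for ch in ("red", "green"):
                mask = masks[(which, ch)]
                target.loc[mask, sample] *= factor[ch]
        # oob readings live on the opposite channel of the probe assignment
        if out.oob_M is not None:
            for df in (out.oob_M, out.oob_U):
                df.loc[oob_chan == "red", sample] *= f_green
                df.loc[oob_chan == "green", sample] *= f_red
        if out.controls is not None:
            sel = out.controls["sample_id"] == sample
            out.controls.loc[sel, "red"] *= f_red
            out.controls.loc[sel, "green"] *= f_green
    return out


def _quantile_normalize_block(block: np.ndarray) -> np.ndarray:
    """Classic across-sample quantile normalisation of one stratum."""
    n, k = block.shape
    ref = np.mean(np.sort(block, axis=0), axis=1)
    out = np.empty_like(block)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(k):
        ranks = rankdata(block[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, ref)  # ties -> average of tied quantiles
    return out


def quantile_normalize(x: IntensitySet, manifest: ProbeManifest) -> IntensitySet:
    """Quantile-normalise across samples, separately per M/U x probe class.

    Four independent strata — (M, type I), (U, type I), (M, type II),
    (U, type II) — so the normalisation never mixes the two assay
    chemistries or the two alleles.  After it, every sample's sorted
    values within a stratum are identical.
    """
    if len(x.samples) < 2:
        warnings.warn("single sample: quantile normalisation is the identity")
        return x.copy()
    is_one = (manifest.table["design_type"] == "I").to_numpy()
    out = x.copy()
    for target in (out.M, out.U):
        for mask in (is_one, ~is_one):
            if mask.any():
                target.iloc[mask] = _quantile_normalize_block(
                    target.iloc[mask].to_numpy(dtype=float))
    return out


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(
    x: IntensitySet,
    manifest: ProbeManifest,
    config: PipelineConfig,
) -> tuple[IntensitySet, BetaMatrix, dict]:
    """Apply the configured steps in order and compute beta values.

    Deterministic given the input, config and seed.  Diagnostics collect
    each stage's output (fit parameters, scaling factors) keyed by stage
    name.
    """
    current = x
    diagnostics: dict = {"steps": list(config.steps),
                         "background_method": config.background_method}
    for step in config.steps:
        try:
            if step == "enmix":
                current, d = enmix_correct(
                    current, manifest, config.background_method,
                    seed=config.subsample_seed,
                    max_fit_points=config.max_fit_points)
                diagnostics["enmix"] = d
            elif step == "dye_bias":
                current = dye_bias_correct(current, manifest)
            elif step == "quantile":
                current = quantile_normalize(current, manifest)
        except ValueError as err:
            raise ValueError(f"pipeline stage {step!r}: {err}") from err
    beta = BetaMatrix(pd.DataFrame(
        compute_beta(current.M.to_numpy(float), current.U.to_numpy(float),
                     offset=config.beta_offset),
        index=current.probe_ids, columns=current.samples))
    if config.beta_hook is not None:
        beta = BetaMatrix(config.beta_hook(beta.values))
    return current, beta, diagnostics
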