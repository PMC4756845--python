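"""Synthetic Infinium-style arrays with known ground truth.

Every observed intensity is drawn from the package's own generative
model: a true signal (exponential for the dim allele, truncated normal
for the bright allele, swapped between M and U by the CpG's
hypo/hyper-methylation state) plus an independent truncated-normal
background per colour channel.  Alongside the intensities the simulator
emits everything a real chip provides — out-of-band readings for type I
probes, 613 negative controls and 186 non-polymorphic controls per
sample, optional bead counts — plus a :class:`GroundTruth` sidecar with
the exact signal and background draws, so correction accuracy can be
measured directly.

Defaults mimic typical scanner output magnitudes (backgrounds of a few
hundred units, bright signals around 10^4) and the 450K design fractions
(28% Infinium I).  They are realism constants of this package, not
measured quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import truncnorm as _sp_truncnorm

from .array_data import IntensitySet, ProbeManifest

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "make_manifest",
    "draw_observed",
    "simulate_array",
    "simulate_duplicates",
    "simulate_titration",
]

#: replicate counts for the default titration design, one per level
_DEFAULT_TITRATION_LEVELS = (0.0, 0.05, 0.10, 0.20, 0.40, 0.50, 0.60, 0.80, 1.0)
_DEFAULT_TITRATION_REPLICATES = (10, 3, 2, 3, 3, 2, 3, 3, 10)


@dataclass
class SimulationSpec:
    """All knobs of the generative model; ``seed`` is mandatory.

    ``lam``/``nu``/``tau`` describe the true-signal components shared by
    all six parts: the dim allele draws from Exp(lam), the bright allele
    from N+(nu, tau^2).  ``fraction_hypo`` sets the proportion of CpGs
    whose M allele is the dim one; because the state swaps the roles of
    M and U, it equals the exponential mixing weight p1 of the M parts
    (and 1 - p1 of the U parts).  Backgrounds are per channel for the
    type I class; type II parts use ``typeII_background_multiplier`` times
    the channel location.  ``dye_imbalance`` multiplies every red-channel
    measurement (signal and background alike).
    """

    seed: int
    n_probes: int = 10_000
    n_samples: int = 2
    fraction_typeI: float = 0.28
    fraction_hypo: float = 0.5
    lam: float = 1.0 / 500.0
    nu: float = 10_000.0
    tau: float = 2_000.0
    bg_red_mu: float = 500.0
    bg_red_sigma: float = 80.0
    bg_green_mu: float = 600.0
    bg_green_sigma: float = 90.0
    typeII_background_multiplier: float = 1.5
    dye_imbalance: float = 1.0
    duplicate_noise_sd: float = 0.05  # lognormal sd of member-level technical noise
    biological_sd: float = 0.15  # lognormal sd of per-CpG, per-subject deviation
    sample_scale_sd: float = 0.1  # lognormal sd of per-sample scanner gain
    bg_level_sd: float = 0.25  # lognormal sd of per-sample, per-channel background level
    titration_levels: tuple = _DEFAULT_TITRATION_LEVELS
    titration_replicates: tuple = _DEFAULT_TITRATION_REPLICATES
    nonspecific_mean: float = 100.0  # small Exp() floor in titration signals
    n_neg_controls: int = 613
    n_nonpoly_controls: int = 186  # split half red-target, half green-target
    nonpoly_mu: float = 5000.0
    nonpoly_sigma: float = 400.0
    with_bead_counts: bool = False
    round_intensities: bool = False

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if not (0.0 < self.fraction_typeI < 1.0):
            raise ValueError("fraction_typeI must lie in (0, 1)")
        if not (0.0 <= self.fraction_hypo <= 1.0):
            raise ValueError("fraction_hypo must lie in [0, 1]")
        for name in ("lam", "nu", "tau", "bg_red_mu", "bg_red_sigma",
                     "bg_green_mu", "bg_green_sigma", "typeII_background_multiplier",
                     "dye_imbalance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(not 0.0 <= m <= 1.0 for m in self.titration_levels):
            raise ValueError("titration levels must lie in [0, 1]")
        if len(self.titration_levels) != len(self.titration_replicates):
            raise ValueError("one replicate count per titration level")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Exact latent draws behind a simulated IntensitySet.

    ``observed = X + Y`` reconstructs the emitted intensities exactly
    (before optional integer rounding).  ``true_beta`` is computed from
    the noise-free signals with the standard offset.
    """

    X_M: pd.DataFrame
    X_U: pd.DataFrame
    Y_M: pd.DataFrame
    Y_U: pd.DataFrame
    true_beta: pd.DataFrame
    cpg_state: pd.Series  # "hypo" / "hyper" per probe ("mix" for titration)
    params: dict = field(default_factory=dict)
    sample_factors: pd.DataFrame | None = None  # gain / bg level per sample


def _trunc_normal(rng, mu, sigma, size):
    return _sp_truncnorm.rvs(-mu / sigma, np.inf, loc=mu, scale=sigma,
                             size=size, random_state=rng)


def draw_observed(model, n: int, seed: int):
    """Draw n observed intensities S = X + Y from a ConvolutionModel.

    Returns ``(s, labels)`` where ``labels`` is True for draws whose
    signal came from the exponential component.  Used for parameter-
    recovery experiments where the truth must be a single known model.
    """
    rng = np.random.default_rng(seed)
    sig, bg = model.signal, model.background
    labels = rng.random(n) < sig.p1
    x = np.where(
        labels,
        rng.exponential(1.0 / sig.lam, n),
        _trunc_normal(rng, sig.nu, sig.tau, n),
    )
    y = _trunc_normal(rng, bg.mu, bg.sigma, n)
    return x + y, labels


def make_manifest(spec: SimulationSpec, rng=None) -> ProbeManifest:
    """Manifest with the configured type I fraction, channels split evenly."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n = spec.n_probes
    n1 = int(round(spec.fraction_typeI * n))
    ids = [f"cg{i:08d}" for i in range(n)]
    design = np.array(["I"] * n1 + ["II"] * (n - n1))
    channel = np.array([""] * n, dtype=object)
    half = n1 // 2
    channel[:half] = "red"
    channel[half:n1] = "green"
    order = rng.permutation(n)
    t = pd.DataFrame({
        "probe_id": ids,
        "design_type": design[order],
        "channel": channel[order],
        "chromosome": "1",
    })
    return ProbeManifest(t)


def _sample_factors(spec: SimulationSpec, rng, n_samples: int) -> pd.DataFrame:
    """Per-sample technical factors: scanner gain and background level.

    The gain multiplies every measurement of a sample; the background
    factor (one per colour channel) multiplies only the noise layer and
    its control/out-of-band draws, emulating chip-to-chip background
    variation.  Both are 1.0 when the corresponding sd is 0.
    """
    def ln(sd):
        return rng.lognormal(0.0, sd, n_samples) if sd > 0 else np.ones(n_samples)

    return pd.DataFrame({
        "gain": ln(spec.sample_scale_sd),
        "bg_red": ln(spec.bg_level_sd),
        "bg_green": ln(spec.bg_level_sd),
    })


def _background_params(spec: SimulationSpec, channel: str, design_type: str):
    mu = spec.bg_red_mu if channel == "red" else spec.bg_green_mu
    sigma = spec.bg_red_sigma if channel == "red" else spec.bg_green_sigma
    if design_type == "II":
        mu = mu * spec.typeII_background_multiplier
    return mu, sigma


def _measurement_channels(manifest: ProbeManifest):
    """(channel of M, channel of U) per probe, as arrays."""
    t = manifest.table
    is_two = (t["design_type"] == "II").to_numpy()
    chan = t["channel"].to_numpy(dtype=object)
    m_chan = np.where(is_two, "green", chan)
    u_chan = np.where(is_two, "red", chan)
    return m_chan, u_chan


def _draw_backgrounds(spec, manifest, rng, factors):
    """Background draws Y for M and U of every probe/sample, dye- and
    sample-factor-scaled."""
    t = manifest.table
    n = len(t)
    n_samples = len(factors)
    m_chan, u_chan = _measurement_channels(manifest)
    design = t["design_type"].to_numpy()
    Y_M = np.empty((n, n_samples))
    Y_U = np.empty((n, n_samples))
    for chan in ("red", "green"):
        per_sample = (factors["gain"] * factors[f"bg_{chan}"]).to_numpy()
        for dt in ("I", "II"):
            mu, sigma = _background_params(spec, chan, dt)
            scale = (spec.dye_imbalance if chan == "red" else 1.0) * per_sample
            for target, cvec in ((Y_M, m_chan), (Y_U, u_chan)):
                mask = (cvec == chan) & (design == dt)
                k = int(mask.sum())
                if k:
                    target[mask] = scale[None, :] * _trunc_normal(rng, mu, sigma, (k, n_samples))
    return Y_M, Y_U


def _signal_pair(spec, rng, hypo_mask, n_samples):
    """True signals (X_M, X_U): dim allele ~ Exp, bright allele ~ N+."""
    n = hypo_mask.size
    exp_m = rng.exponential(1.0 / spec.lam, (n, n_samples))
    exp_u = rng.exponential(1.0 / spec.lam, (n, n_samples))
    nrm_m = _trunc_normal(rng, spec.nu, spec.tau, (n, n_samples))
    nrm_u = _trunc_normal(rng, spec.nu, spec.tau, (n, n_samples))
    h = hypo_mask[:, None]
    X_M = np.where(h, exp_m, nrm_m)
    X_U = np.where(h, nrm_u, exp_u)
    return X_M, X_U


def _dye_scale_signals(spec, manifest, X_M, X_U):
    """Fold the red-channel dye factor into the signal draws."""
    if spec.dye_imbalance == 1.0:
        return X_M, X_U
    m_chan, u_chan = _measurement_channels(manifest)
    X_M = np.where((m_chan == "red")[:, None], spec.dye_imbalance * X_M, X_M)
    X_U = np.where((u_chan == "red")[:, None], spec.dye_imbalance * X_U, X_U)
    return X_M, X_U


def _controls_table(spec, rng, sample_ids, factors):
    """Negative and non-polymorphic control draws for every sample."""
    rows = []
    dye = spec.dye_imbalance
    n_np = spec.n_nonpoly_controls // 2
    for j, sid in enumerate(sample_ids):
        g = factors["gain"].iloc[j]
        f_red = g * factors["bg_red"].iloc[j]
        f_green = g * factors["bg_green"].iloc[j]
        red = dye * f_red * _trunc_normal(rng, spec.bg_red_mu, spec.bg_red_sigma, spec.n_neg_controls)
        green = f_green * _trunc_normal(rng, spec.bg_green_mu, spec.bg_green_sigma, spec.n_neg_controls)
        rows.append(pd.DataFrame({
            "sample_id": sid, "control_type": "negative", "red": red, "green": green,
        }))
        # red-target: bright on red, background on green (and vice versa)
        np_red = dye * g * _trunc_normal(rng, spec.nonpoly_mu, spec.nonpoly_sigma, n_np)
        np_red_bg = f_green * _trunc_normal(rng, spec.bg_green_mu, spec.bg_green_sigma, n_np)
        rows.append(pd.DataFrame({
            "sample_id": sid, "control_type": "nonpolymorphic_red",
            "red": np_red, "green": np_red_bg,
        }))
        np_green = g * _trunc_normal(rng, spec.nonpoly_mu, spec.nonpoly_sigma, n_np)
        np_green_bg = dye * f_red * _trunc_normal(rng, spec.bg_red_mu, spec.bg_red_sigma, n_np)
        rows.append(pd.DataFrame({
            "sample_id": sid, "control_type": "nonpolymorphic_green",
            "red": np_green_bg, "green": np_green,
        }))
    return pd.concat(rows, ignore_index=True)


def _oob_matrices(spec, rng, manifest, sample_ids, factors):
    """Out-of-band draws: a type I probe's unused channel reads pure background."""
    type1 = manifest.ids_of("I")
    t = manifest.table.set_index("probe_id").loc[type1]
    chan = t["channel"].to_numpy(dtype=object)
    n1 = len(type1)
    oob = {}
    for name in ("oob_M", "oob_U"):
        vals = np.empty((n1, len(sample_ids)))
        for c in ("red", "green"):
            opp = "green" if c == "red" else "red"
            mu, sigma = _background_params(spec, opp, "I")
            per_sample = (factors["gain"] * factors[f"bg_{opp}"]).to_numpy()
            scale = (spec.dye_imbalance if opp == "red" else 1.0) * per_sample
            mask = chan == c
            k = int(mask.sum())
            if k:
                vals[mask] = scale[None, :] * _trunc_normal(rng, mu, sigma, (k, len(sample_ids)))
        oob[name] = pd.DataFrame(vals, index=type1, columns=sample_ids)
    return oob


def _assemble(spec, manifest, sample_ids, X_M, X_U, Y_M, Y_U, rng, state_labels,
              factors):
    probes = manifest.probe_ids
    S_M = X_M + Y_M
    S_U = X_U + Y_U
    if spec.round_intensities:
        S_M = np.round(S_M)
        S_U = np.round(S_U)
    M = pd.DataFrame(S_M, index=probes, columns=sample_ids)
    U = pd.DataFrame(S_U, index=probes, columns=sample_ids)
    oob = _oob_matrices(spec, rng, manifest, sample_ids, factors)
    controls = _controls_table(spec, rng, sample_ids, factors)
    kw = {}
    if spec.with_bead_counts:
        kw["bead_count_M"] = pd.DataFrame(
            rng.poisson(14, size=S_M.shape) + 1, index=probes, columns=sample_ids)
        kw["bead_count_U"] = pd.DataFrame(
            rng.poisson(14, size=S_U.shape) + 1, index=probes, columns=sample_ids)
    x = IntensitySet(M=M, U=U, controls=controls, **oob, **kw)
    frame = lambda a: pd.DataFrame(a, index=probes, columns=sample_ids)
    truth = GroundTruth(
        X_M=frame(X_M), X_U=frame(X_U), Y_M=frame(Y_M), Y_U=frame(Y_U),
        true_beta=frame(X_M / (X_M + X_U + 100.0)),
        cpg_state=pd.Series(state_labels, index=probes),
        params=spec.to_dict(),
        sample_factors=factors.set_axis(sample_ids),
    )
    return x, truth


def simulate_array(spec: SimulationSpec) -> tuple[IntensitySet, GroundTruth]:
    """Independent samples under the generative model S = X + Y.

    Each CpG gets a methylation state shared by all samples (hypo: M dim /
    U bright; hyper: the reverse), giving the characteristic bimodal beta
    distribution; signals are redrawn per sample, backgrounds always
    independent.
    """
    rng = np.random.default_rng(spec.seed)
    manifest = make_manifest(spec, rng)
    sample_ids = [f"sample{i + 1:03d}" for i in range(spec.n_samples)]
    hypo = rng.random(spec.n_probes) < spec.fraction_hypo
    factors = _sample_factors(spec, rng, spec.n_samples)
    X_M, X_U = _signal_pair(spec, rng, hypo, spec.n_samples)
    X_M *= factors["gain"].to_numpy()[None, :]
    X_U *= factors["gain"].to_numpy()[None, :]
    X_M, X_U = _dye_scale_signals(spec, manifest, X_M, X_U)
    Y_M, Y_U = _draw_backgrounds(spec, manifest, rng, factors)
    labels = np.where(hypo, "hypo", "hyper")
    x, truth = _assemble(spec, manifest, sample_ids, X_M, X_U, Y_M, Y_U, rng, labels,
                         factors)
    truth.params["manifest"] = None  # manifest returned separately
    x.manifest = manifest  # convenience attribute
    return x, truth


def simulate_duplicates(spec: SimulationSpec, n_pairs: int):
    """Duplicate pairs: shared true signal, independent technical layers.

    Each CpG carries a baseline signal level drawn once from the mixture
    (methylation is characteristic of the locus, which is what makes raw
    beta correlations between *unrelated* samples so high); each pair's
    subject deviates from it by a shared lognormal factor
    (``biological_sd``), and each member adds independent lognormal
    technical noise (``duplicate_noise_sd``).  Backgrounds, out-of-band
    values and controls are drawn independently per member, mirroring
    independent labelling, hybridisation and scanning.
    """
    if n_pairs < 1:
        raise ValueError("need at least one duplicate pair")
    rng = np.random.default_rng(spec.seed)
    manifest = make_manifest(spec, rng)
    hypo = rng.random(spec.n_probes) < spec.fraction_hypo
    base_M, base_U = _signal_pair(spec, rng, hypo, 1)
    sample_ids = []
    pairs = []
    blocks_XM, blocks_XU = [], []
    for p in range(n_pairs):
        a, b = f"pair{p + 1:02d}_a", f"pair{p + 1:02d}_b"
        sample_ids += [a, b]
        pairs.append((a, b))
        if spec.biological_sd > 0:
            xm = base_M * rng.lognormal(0.0, spec.biological_sd, base_M.shape)
            xu = base_U * rng.lognormal(0.0, spec.biological_sd, base_U.shape)
        else:
            xm, xu = base_M, base_U
        for _ in range(2):
            if spec.duplicate_noise_sd > 0:
                noise_m = rng.lognormal(0.0, spec.duplicate_noise_sd, xm.shape)
                noise_u = rng.lognormal(0.0, spec.duplicate_noise_sd, xu.shape)
            else:
                noise_m = noise_u = 1.0
            blocks_XM.append(xm * noise_m)
            blocks_XU.append(xu * noise_u)
    X_M = np.concatenate(blocks_XM, axis=1)
    X_U = np.concatenate(blocks_XU, axis=1)
    factors = _sample_factors(spec, rng, 2 * n_pairs)
    X_M *= factors["gain"].to_numpy()[None, :]
    X_U *= factors["gain"].to_numpy()[None, :]
    X_M, X_U = _dye_scale_signals(spec, manifest, X_M, X_U)
    Y_M, Y_U = _draw_backgrounds(spec, manifest, rng, factors)
    labels = np.where(hypo, "hypo", "hyper")
    x, truth = _assemble(spec, manifest, sample_ids, X_M, X_U, Y_M, Y_U, rng, labels,
                         factors)
    x.manifest = manifest
    from .evaluation import DuplicateDesign

    return x, DuplicateDesign(pairs=pairs), truth


def simulate_titration(spec: SimulationSpec):
    """Laboratory titration standards at fixed methylation levels.

    For a sample at level m every CpG's methylated signal scales with m
    and the unmethylated signal with 1 - m (full-scale intensities drawn
    from the bright component), plus a small exponential non-specific
    floor; the default design runs the levels 0..100% with replicate
    counts (10,3,2,3,3,2,3,3,10) — 39 samples.
    """
    rng = np.random.default_rng(spec.seed)
    manifest = make_manifest(spec, rng)
    sample_ids, levels = [], []
    for lev, n_rep in zip(spec.titration_levels, spec.titration_replicates):
        for r in range(n_rep):
            sample_ids.append(f"titr{int(round(100 * lev)):03d}_r{r + 1:02d}")
            levels.append(lev)
    n_samples = len(sample_ids)
    n = spec.n_probes
    T_M = _trunc_normal(rng, spec.nu, spec.tau, (n, n_samples))
    T_U = _trunc_normal(rng, spec.nu, spec.tau, (n, n_samples))
    ns_M = rng.exponential(spec.nonspecific_mean, (n, n_samples))
    ns_U = rng.exponential(spec.nonspecific_mean, (n, n_samples))
    lev_arr = np.asarray(levels)[None, :]
    factors = _sample_factors(spec, rng, n_samples)
    X_M = (lev_arr * T_M + ns_M) * factors["gain"].to_numpy()[None, :]
    X_U = ((1.0 - lev_arr) * T_U + ns_U) * factors["gain"].to_numpy()[None, :]
    X_M, X_U = _dye_scale_signals(spec, manifest, X_M, X_U)
    Y_M, Y_U = _draw_backgrounds(spec, manifest, rng, factors)
    x, truth = _assemble(spec, manifest, sample_ids, X_M, X_U, Y_M, Y_U, rng,
                         np.full(n, "mix"), factors)
    x.manifest = manifest
    from .evaluation import TitrationDesign

    return x, TitrationDesign(levels=dict(zip(sample_ids, levels))), truth
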