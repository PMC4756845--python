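"""Parameter estimation for the observed-intensity model.

Two kinds of estimation live here:

* **Background** ``(mu, sigma)`` of the truncated-normal noise, by three
  routes: internal negative-control probes (``neg``), out-of-band
  intensities of opposite-channel type I probes (``oob``), or a full
  maximum-likelihood fit on the pooled M+U data of one probe class
  (``est``).  ``neg``/``oob`` are per-channel; only ``est`` resolves
  Infinium I and II probe classes separately.

* **Signal mixture** ``(p1, lam, nu, tau)`` given a fixed background, by
  EM over the latent exponential-vs-normal component label.  The E-step is
  the component posterior of the convolution model; the M-step updates
  ``p1`` in closed form and improves ``lam`` and ``(nu, tau)`` (and
  ``(mu, sigma)`` when the background is free) by bounded numerical
  maximisation of the expected complete-data log-likelihood — a
  generalised EM, so the observed log-likelihood never decreases.

Fitting is deterministic: initial values are data quantiles, and any
subsampling uses a caller-provided seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import log_ndtr
from scipy.stats import truncnorm as _sp_truncnorm

from .core_model import (
    ConvolutionModel,
    SignalMixtureParams,
    TruncNormalParams,
    _component_logpdfs,
    _log_gauss_mass,
)

__all__ = [
    "BackgroundParams",
    "FitDiagnostics",
    "estimate_background_neg",
    "estimate_background_oob",
    "estimate_background_est",
    "fit_signal_mixture",
    "fit_convolution_model",
]

_MAD_TO_SIGMA = 1.4826  # consistency factor: sigma = 1.4826 * MAD for a normal
_P1_CLAMP = 1e-4
_SIGMA_FLOOR = 1.0  # intensity units; scanner quantisation scale


@dataclass(frozen=True)
class BackgroundParams:
    """Truncated-normal background N+(mu, sigma^2) for one channel.

    ``probe_class`` is ``"both"`` for the channel-level ``neg``/``oob``
    routes; only the ``est`` route estimates Infinium I and II classes
    separately.
    """

    mu: float
    sigma: float
    channel: str  # {"red", "green"}
    probe_class: str = "both"  # {"typeI", "typeII", "both"}
    method: str = "neg"  # {"neg", "oob", "est"}

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.channel not in ("red", "green"):
            raise ValueError(f"channel must be 'red' or 'green', got {self.channel!r}")
        if self.method not in ("neg", "oob", "est"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.probe_class not in ("typeI", "typeII", "both"):
            raise ValueError(f"unknown probe_class {self.probe_class!r}")
        if self.method != "est" and self.probe_class != "both":
            raise ValueError("only the est route estimates per-probe-class backgrounds")

    def as_truncnormal(self) -> TruncNormalParams:
        return TruncNormalParams(self.mu, self.sigma)


@dataclass
class FitDiagnostics:
    """Per-fit convergence record; ``loglik_trace`` is non-decreasing."""

    loglik_trace: list = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False
    n_points: int = 0
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "loglik_trace": [float(v) for v in self.loglik_trace],
            "n_iter": int(self.n_iter),
            "converged": bool(self.converged),
            "n_points": int(self.n_points),
            "flags": list(self.flags),
        }


# ---------------------------------------------------------------------------
# robust truncated-normal background estimation (neg / oob routes)
# ---------------------------------------------------------------------------

def _truncnorm_median_mad(mu: float, sigma: float) -> tuple[float, float]:
    """Median and MAD of N(mu, sigma^2) truncated at 0 (numeric, scalar)."""
    a = -mu / sigma
    med = _sp_truncnorm.ppf(0.5, a, np.inf, loc=mu, scale=sigma)

    def cdf(x):
        return _sp_truncnorm.cdf(x, a, np.inf, loc=mu, scale=sigma)

    def mass_within(d):
        return cdf(med + d) - cdf(max(med - d, 0.0)) - 0.5

    mad = optimize.brentq(mass_within, 1e-9 * sigma, 20 * sigma)
    return float(med), float(mad)


def _robust_truncnorm_estimate(values: np.ndarray) -> tuple[float, float]:
    """Median/MAD location-scale, then one truncation-aware refinement.

    The raw median and scaled MAD are consistent for (mu, sigma) only when
    the truncation at zero removes negligible mass; the refinement inverts
    the median/MAD map of N+(m0, s0^2) once, which removes the first-order
    bias when the background sits close to zero.
    """
    if np.ptp(values) <= 0:
        raise ValueError("zero scale: input values are all identical")
    m0 = float(np.median(values))
    s0 = _MAD_TO_SIGMA * float(np.median(np.abs(values - m0)))
    if s0 <= _SIGMA_FLOOR:
        # degenerate spread (e.g. heavy ties): no refinement is possible
        return m0, _SIGMA_FLOOR
    med_t, mad_t = _truncnorm_median_mad(m0, s0)
    mu = m0 - (med_t - m0)
    sigma = s0 * (s0 / (_MAD_TO_SIGMA * mad_t))
    return mu, max(sigma, _SIGMA_FLOOR)


def _validated_positive(values, min_n: int, what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    arr = arr[np.isfinite(arr)]
    if arr.size < min_n:
        raise ValueError(
            f"{what}: need at least {min_n} values for a stable estimate, got {arr.size}"
        )
    if np.any(arr < 0):
        raise ValueError(f"{what}: negative intensities are not allowed")
    return arr


def estimate_background_neg(neg_control_intensities, channel: str) -> BackgroundParams:
    """Background (mu, sigma) from the negative-control probes of one channel.

    The 450K design carries 613 negative-control probes per channel; a
    robust median/MAD estimate with a single truncation-aware refinement
    is used so stray hybridisation artifacts cannot inflate the estimate.
    """
    arr = _validated_positive(neg_control_intensities, 20, "negative controls")
    mu, sigma = _robust_truncnorm_estimate(arr)
    return BackgroundParams(mu, sigma, channel=channel, method="neg")


def estimate_background_oob(oob_intensities, channel: str) -> BackgroundParams:
    """Background (mu, sigma) from out-of-band type I intensities.

    The green-channel background is estimated from the out-of-band
    measurements of red-assigned Infinium I probes and vice versa; with
    >10^5 values the estimate is far more precise than the negative-control
    route.  Same estimator as :func:`estimate_background_neg`.
    """
    arr = _validated_positive(oob_intensities, 20, "out-of-band intensities")
    mu, sigma = _robust_truncnorm_estimate(arr)
    return BackgroundParams(mu, sigma, channel=channel, method="oob")


# ---------------------------------------------------------------------------
# EM fitting of the convolution model
# ---------------------------------------------------------------------------

def _observed_loglik(s: np.ndarray, p1: float, lf1: np.ndarray, lf2: np.ndarray) -> float:
    with np.errstate(divide="ignore"):
        la = np.log(p1) + lf1
        lb = np.log1p(-p1) + lf2
    return float(np.sum(np.logaddexp(la, lb)))


def _posterior_from_logpdfs(p1: float, lf1: np.ndarray, lf2: np.ndarray) -> np.ndarray:
    log_ratio = (np.log1p(-p1) + lf2) - (np.log(p1) + lf1)
    return np.exp(-np.logaddexp(0.0, log_ratio))


def _q_exp(s, w, lam, mu, sigma):
    """Expected complete log-likelihood term of the exponential component."""
    if lam <= 0:
        return -np.inf
    wsum = w.sum()
    if wsum <= 0:
        return 0.0
    m1 = s - mu - sigma * sigma * lam
    beta1 = (mu + sigma * sigma * lam) / sigma
    logmass = _log_gauss_mass(-m1 / sigma, np.full_like(s, beta1))
    const = np.log(lam) + 0.5 * (sigma * lam) ** 2 + mu * lam - log_ndtr(mu / sigma)
    return float(wsum * const - lam * np.dot(w, s) + np.dot(w, logmass))


def _q_norm(s, w, nu, tau, mu, sigma):
    """Expected complete log-likelihood term of the truncated-normal component."""
    if tau <= 0:
        return -np.inf
    wsum = w.sum()
    if wsum <= 0:
        return 0.0
    var_sum = sigma * sigma + tau * tau
    sc = sigma * tau / np.sqrt(var_sum)
    m2 = (nu * sigma * sigma + (s - mu) * tau * tau) / var_sum
    logmass = _log_gauss_mass(-m2 / sc, (s - m2) / sc)
    const = (
        -0.5 * np.log(2.0 * np.pi * var_sum)
        - log_ndtr(nu / tau)
        - log_ndtr(mu / sigma)
    )
    quad_term = -0.5 * np.dot(w, (s - mu - nu) ** 2) / var_sum
    return float(wsum * const + quad_term + np.dot(w, logmass))


def _subsample(s: np.ndarray, max_points: int, seed: int) -> np.ndarray:
    if max_points is None or s.size <= max_points:
        return s
    rng = np.random.default_rng(seed)
    return rng.choice(s, size=max_points, replace=False)


def fit_convolution_model(
    part_intensities,
    background: BackgroundParams | None = None,
    *,
    channel: str = "red",
    probe_class: str = "both",
    tol: float = 1e-6,
    max_iter: int = 1000,
    max_points: int = 50_000,
    seed: int = 0,
) -> tuple[ConvolutionModel, FitDiagnostics]:
    """Fit the full observed-intensity model by (generalised) EM.

    With ``background`` given, only the signal mixture (p1, lam, nu, tau)
    is free; with ``background=None`` the background (mu, sigma) is
    estimated jointly (the ``est`` route), under the identifiability guard
    ``nu >= mu + 2*sigma`` that prevents the bright-signal normal from
    swapping roles with the background.
    """
    s_all = np.asarray(part_intensities, dtype=float).ravel()
    s_all = s_all[np.isfinite(s_all) & (s_all > 0)]
    min_n = 5000 if background is None else 1000
    what = "est background fit" if background is None else "signal mixture fit"
    if s_all.size < min_n:
        raise ValueError(f"{what}: need at least {min_n} positive values, got {s_all.size}")
    s = np.sort(_subsample(s_all, max_points, seed))
    if np.ptp(s) <= 0:
        raise ValueError("zero scale: all intensities identical")

    # deterministic scale-aware initialisation from data quantiles
    p1 = 0.5
    lam = 1.0 / max(float(np.median(s)), 1e-6)
    nu = float(np.percentile(s, 75))
    upper = s[s > np.median(s)]
    tau = _MAD_TO_SIGMA * float(np.median(np.abs(upper - np.median(upper))))
    tau = min(max(tau, _SIGMA_FLOOR), 1.9 * nu)  # start inside the nu >= tau/2 guard

    free_bg = background is None
    if free_bg:
        low = s[s <= np.percentile(s, 10)]
        mu = float(np.percentile(s, 2))
        sigma = max(_MAD_TO_SIGMA * float(np.median(np.abs(low - np.median(low)))), _SIGMA_FLOOR)
        nu = max(nu, mu + 2.0 * sigma + _SIGMA_FLOOR)
    else:
        mu, sigma = background.mu, background.sigma

    diag = FitDiagnostics(n_points=int(s.size))
    lam_bounds = (1e-8, 10.0)
    s_med = float(np.median(s))

    def model_of(p1_, lam_, nu_, tau_, mu_, sigma_):
        return ConvolutionModel(
            SignalMixtureParams(p1_, lam_, TruncNormalParams(nu_, tau_)),
            TruncNormalParams(mu_, sigma_),
        )

    prev_ll = -np.inf
    for it in range(max_iter):
        lf1, lf2 = _component_logpdfs(s, model_of(p1, lam, nu, tau, mu, sigma))
        ll = _observed_loglik(s, p1, lf1, lf2)
        diag.loglik_trace.append(ll)
        diag.n_iter = it + 1
        if it > 0 and abs(ll - prev_ll) < tol * (abs(prev_ll) + 1.0):
            diag.converged = True
            break
        prev_ll = ll

        # ----- E-step ---------------------------------------------------
        w = _posterior_from_logpdfs(p1, lf1, lf2)

        # ----- M-step (block coordinate ascent on Q) --------------------
        p1 = float(np.clip(w.mean(), _P1_CLAMP, 1.0 - _P1_CLAMP))

        # exponential rate: points with negligible weight are dropped for speed
        idx1 = w > 1e-12
        s1, w1 = s[idx1], w[idx1]
        if w1.sum() > 1e-9:
            cur = _q_exp(s1, w1, lam, mu, sigma)
            res = optimize.minimize_scalar(
                lambda loglam: -_q_exp(s1, w1, np.exp(loglam), mu, sigma),
                bounds=(
                    max(np.log(lam) - 2.0, np.log(lam_bounds[0])),
                    min(np.log(lam) + 2.0, np.log(lam_bounds[1])),
                ),
                method="bounded",
                options={"maxiter": 30, "xatol": 1e-7},
            )
            if np.isfinite(res.fun) and -res.fun > cur:
                lam = float(np.exp(res.x))

        # bright-normal location/scale.  Identifiability guards: nu >= tau/2
        # keeps the component a genuinely bright peaked signal (otherwise a
        # heavily-truncated far-left normal can mimic a second exponential);
        # under a free background nu >= mu + 2*sigma additionally prevents a
        # signal/background swap.
        idx2 = (1.0 - w) > 1e-12
        s2, w2 = s[idx2], 1.0 - w[idx2]
        nu_floor = (mu + 2.0 * sigma) if free_bg else 0.0
        if w2.sum() > 1e-9:
            def neg_q2(x):
                nu_, tau_ = x[0], np.exp(x[1])
                if nu_ < max(nu_floor, 0.5 * tau_) or not (_SIGMA_FLOOR <= tau_ <= 1e6):
                    return 1e300
                return -_q_norm(s2, w2, nu_, tau_, mu, sigma)

            cur = _q_norm(s2, w2, nu, tau, mu, sigma)
            res = optimize.minimize(
                neg_q2,
                x0=np.array([nu, np.log(tau)]),
                method="Nelder-Mead",
                options={"maxiter": 40, "maxfev": 60, "xatol": 1e-4, "fatol": 1e-8},
            )
            if np.isfinite(res.fun) and -res.fun > cur:
                nu, tau = float(res.x[0]), float(np.exp(res.x[1]))

        # background block (est route only).  mu >= -2*sigma keeps the
        # background a genuine (half-)bump near zero — a far-left truncated
        # normal would otherwise mimic, and absorb, the exponential signal;
        # mu <= median(s) pins it to the dim end of the data.
        if free_bg:
            def neg_q_bg(x):
                mu_, sigma_ = x[0], np.exp(x[1])
                if not (_SIGMA_FLOOR * 1e-1 <= sigma_ <= 1e5):
                    return 1e300
                if mu_ < -2.0 * sigma_ or mu_ > s_med:
                    return 1e300
                if nu < mu_ + 2.0 * sigma_:
                    return 1e300
                return -(
                    _q_exp(s1, w1, lam, mu_, sigma_)
                    + _q_norm(s2, w2, nu, tau, mu_, sigma_)
                )

            cur = _q_exp(s1, w1, lam, mu, sigma) + _q_norm(s2, w2, nu, tau, mu, sigma)
            res = optimize.minimize(
                neg_q_bg,
                x0=np.array([mu, np.log(sigma)]),
                method="Nelder-Mead",
                options={"maxiter": 40, "maxfev": 60, "xatol": 1e-4, "fatol": 1e-8},
            )
            if np.isfinite(res.fun) and -res.fun > cur:
                mu, sigma = float(res.x[0]), float(np.exp(res.x[1]))
                sigma = max(sigma, _SIGMA_FLOOR)

    else:
        diag.flags.append("max_iter reached without convergence; best-so-far returned")

    # Degenerate-mixture guard: when one component explains the data within
    # the BIC parameter-count penalty of the two-component fit, the mixture
    # weight is unidentifiable and is snapped to the boundary.  This makes a
    # pure-exponential part come back as p1 ~ 1 instead of an arbitrary
    # split with a redundant decay-like normal component.
    ones = np.ones_like(s)
    ll_fit = diag.loglik_trace[-1]
    log_n = np.log(s.size)

    res = optimize.minimize_scalar(
        lambda loglam: -_q_exp(s, ones, np.exp(loglam), mu, sigma),
        bounds=(np.log(lam_bounds[0]), np.log(lam_bounds[1])),
        method="bounded",
        options={"maxiter": 60, "xatol": 1e-9},
    )
    if np.isfinite(res.fun) and -res.fun >= ll_fit - 1.5 * log_n:  # 3 params saved
        p1, lam = 1.0 - _P1_CLAMP, float(np.exp(res.x))
        diag.flags.append("collapsed to exponential-only component")
    else:
        nu_floor = (mu + 2.0 * sigma) if free_bg else 0.0

        def neg_pure_norm(x):
            nu_, tau_ = x[0], np.exp(x[1])
            if nu_ < max(nu_floor, 0.5 * tau_) or not (_SIGMA_FLOOR <= tau_ <= 1e6):
                return 1e300
            return -_q_norm(s, ones, nu_, tau_, mu, sigma)

        res = optimize.minimize(
            neg_pure_norm,
            x0=np.array([nu, np.log(tau)]),
            method="Nelder-Mead",
            options={"maxiter": 200, "maxfev": 300, "xatol": 1e-6, "fatol": 1e-10},
        )
        if np.isfinite(res.fun) and -res.fun >= ll_fit - 1.0 * log_n:  # 2 params saved
            p1 = _P1_CLAMP
            nu, tau = float(res.x[0]), float(np.exp(res.x[1]))
            diag.flags.append("collapsed to normal-only component")

    if p1 <= _P1_CLAMP or p1 >= 1.0 - _P1_CLAMP:
        diag.flags.append("p1 clamped at boundary")

    model = model_of(p1, lam, nu, tau, mu, sigma)
    return model, diag


def fit_signal_mixture(
    part_intensities,
    background: BackgroundParams,
    *,
    tol: float = 1e-6,
    max_iter: int = 1000,
    max_points: int = 50_000,
    seed: int = 0,
) -> tuple[SignalMixtureParams, FitDiagnostics]:
    """EM fit of the signal mixture (p1, lam, nu, tau) at fixed background."""
    model, diag = fit_convolution_model(
        part_intensities,
        background,
        tol=tol,
        max_iter=max_iter,
        max_points=max_points,
        seed=seed,
    )
    return model.signal, diag


def estimate_background_est(
    part_intensities,
    channel: str,
    probe_class: str,
    *,
    tol: float = 1e-6,
    max_iter: int = 1000,
    max_points: int = 50_000,
    seed: int = 0,
) -> BackgroundParams:
    """Background (mu, sigma) from the pooled M+U data of one probe class.

    Full maximum-likelihood fit of the convolution model with the
    background free; only this route resolves the systematically higher
    Infinium II background.  Needs >= 5000 pooled values.
    """
    model, diag = fit_convolution_model(
        part_intensities,
        None,
        tol=tol,
        max_iter=max_iter,
        max_points=max_points,
        seed=seed,
    )
    bg = model.background
    return BackgroundParams(bg.mu, bg.sigma, channel=channel, probe_class=probe_class, method="est")
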