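"""Shared fixtures and the independent quadrature oracle.

The oracle evaluates the conditional mean E(X|S=s) and the observed
density by adaptive quadrature on the log-rescaled integrand (absolute
tolerance 1e-14 after peak rescaling), fully independent of the closed
forms under test.
"""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from enmix import SimulationSpec, simulate_array
from enmix.core_model import ConvolutionModel, SignalMixtureParams, TruncNormalParams


def quad_oracle(s: float, model: ConvolutionModel):
    """(E(X|S=s), f_S(s)) by adaptive quadrature of the defining integrals.

    The integrand f_X(x) f_Y(s-x) is restricted to the window where the
    background density is non-negligible and rescaled by its peak so the
    quadrature never underflows, even 20 signal scales into the tail.
    """
    sig, bg = model.signal, model.background
    lo = max(0.0, s - bg.mu - 15.0 * bg.sigma)
    hi = min(s, s - bg.mu + 15.0 * bg.sigma)
    if hi <= lo:
        lo, hi = 0.0, s
    l_znu = norm.logcdf(sig.nu / sig.tau)
    l_zmu = norm.logcdf(bg.mu / bg.sigma)

    def log_integrand(x):
        x = np.asarray(x, dtype=float)
        if sig.p1 > 0:
            t1 = np.log(sig.p1) + np.log(sig.lam) - sig.lam * x
        else:
            t1 = np.full_like(x, -np.inf)
        if sig.p1 < 1:
            t2 = np.log1p(-sig.p1) + norm.logpdf(x, sig.nu, sig.tau) - l_znu
        else:
            t2 = np.full_like(x, -np.inf)
        return (np.logaddexp(t1, t2)
                + norm.logpdf(s - x, bg.mu, bg.sigma) - l_zmu)

    c = float(np.max(log_integrand(np.linspace(lo, hi, 1001))))
    den = quad(lambda x: np.exp(log_integrand(x) - c), lo, hi,
               epsabs=1e-14, epsrel=1e-11, limit=500)[0]
    num = quad(lambda x: x * np.exp(log_integrand(x) - c), lo, hi,
               epsabs=1e-14, epsrel=1e-11, limit=500)[0]
    return num / den, float(np.exp(c) * den)


def random_model(rng) -> ConvolutionModel:
    """A model with parameters in the realistic scanner ranges."""
    return ConvolutionModel(
        SignalMixtureParams(
            p1=rng.uniform(0.2, 0.8),
            lam=1.0 / rng.uniform(1e3, 1e4),
            normal=TruncNormalParams(rng.uniform(3000, 20000), rng.uniform(500, 5000)),
        ),
        TruncNormalParams(rng.uniform(200, 1500), rng.uniform(30, 300)),
    )


@pytest.fixture(scope="session")
def small_array():
    """3-sample, 8000-probe simulated array with bead counts and truth."""
    spec = SimulationSpec(seed=101, n_probes=8000, n_samples=3, with_bead_counts=True)
    x, truth = simulate_array(spec)
    return x, x.manifest, truth


@pytest.fixture(scope="session")
def small_beta(small_array):
    from enmix import compute_beta

    x, manifest, truth = small_array
    return pd.DataFrame(
        compute_beta(x.M.to_numpy(float), x.U.to_numpy(float)),
        index=x.probe_ids, columns=x.samples,
    )
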