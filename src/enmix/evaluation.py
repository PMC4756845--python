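"""Performance metrics for preprocessing comparisons.

Raw beta-value correlation between any two blood samples is ~0.99 simply
because the bimodal methylation pattern is shared genome-wide, so it
cannot discriminate preprocessing quality.  The metrics here remove that
shared structure:

* **mean-centered correlation** — subtract each CpG's across-sample mean
  before correlating a duplicate pair; unrelated pairs then score ~0.
* **mean absolute beta difference** — average |beta_a - beta_b| over
  CpGs, reported in percentage points.
* **titration deviation** — signed median difference between measured
  beta and the known methylation level of laboratory standards,
  per level; background inflation pushes it positive at 0% and negative
  at 100%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .array_data import BetaMatrix

__all__ = [
    "DuplicateDesign",
    "TitrationDesign",
    "mean_centered_correlation",
    "mean_abs_beta_diff",
    "titration_deviation",
    "compare_methods",
]


@dataclass
class DuplicateDesign:
    """Pairs of sample ids that are technical duplicates."""

    pairs: list

    def __post_init__(self) -> None:
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"a duplicate pair needs two distinct ids, got {a!r} twice")

    @classmethod
    def read_csv(cls, path) -> "DuplicateDesign":
        t = pd.read_csv(path)
        return cls(pairs=list(zip(t.iloc[:, 0].astype(str), t.iloc[:, 1].astype(str))))

    def to_csv(self, path) -> None:
        pd.DataFrame(self.pairs, columns=["sample_a", "sample_b"]).to_csv(path, index=False)


@dataclass
class TitrationDesign:
    """Expected methylation level per sample id, each in [0, 1]."""

    levels: dict

    def __post_init__(self) -> None:
        for sid, lev in self.levels.items():
            if not 0.0 <= lev <= 1.0:
                raise ValueError(f"level for {sid!r} outside [0, 1]: {lev}")

    @classmethod
    def read_csv(cls, path) -> "TitrationDesign":
        t = pd.read_csv(path)
        return cls(levels=dict(zip(t.iloc[:, 0].astype(str), t.iloc[:, 1].astype(float))))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"sample_id": list(self.levels), "level": list(self.levels.values())}
        ).to_csv(path, index=False)


def _beta_frame(betas) -> pd.DataFrame:
    return betas.values if isinstance(betas, BetaMatrix) else betas


def mean_centered_correlation(betas, pair) -> float:
    """Pearson correlation of a pair after per-CpG mean-centering.

    The mean is taken across *all* samples in the matrix, so at least 3
    samples are required (with exactly the 2 pair samples, centering maps
    the columns onto mirror images and the correlation is identically -1).
    CpGs with a missing value in either column are dropped pairwise.
    """
    b = _beta_frame(betas)
    a_id, b_id = pair
    if b.shape[1] < 3:
        raise ValueError("mean-centered correlation needs >= 3 samples for centering")
    for sid in (a_id, b_id):
        if sid not in b.columns:
            raise KeyError(f"sample {sid!r} not in beta matrix")
    centered = b.sub(b.mean(axis=1), axis=0)
    xa = centered[a_id].to_numpy(dtype=float)
    xb = centered[b_id].to_numpy(dtype=float)
    ok = np.isfinite(xa) & np.isfinite(xb)
    xa, xb = xa[ok], xb[ok]
    if xa.std() == 0 or xb.std() == 0:
        raise ValueError("zero variance after centering; correlation undefined")
    return float(np.corrcoef(xa, xb)[0, 1])


def mean_abs_beta_diff(betas, pair) -> float:
    """Average |beta_a - beta_b| over CpGs, in percentage points."""
    b = _beta_frame(betas)
    a_id, b_id = pair
    for sid in (a_id, b_id):
        if sid not in b.columns:
            raise KeyError(f"sample {sid!r} not in beta matrix")
    d = (b[a_id] - b[b_id]).abs().to_numpy(dtype=float)
    return float(np.nanmean(d) * 100.0)


def titration_deviation(betas, design: TitrationDesign) -> pd.Series:
    """Signed per-level median of (beta - expected level), in beta units.

    Pooled over CpGs and replicate samples at each level.  Positive at the
    unmethylated extreme / negative at the methylated extreme is the
    signature of uncorrected background.
    """
    b = _beta_frame(betas)
    missing = [sid for sid in design.levels if sid not in b.columns]
    if missing:
        raise KeyError(f"titration samples missing from beta matrix: {missing[:5]}")
    out = {}
    for lev in sorted(set(design.levels.values())):
        cols = [sid for sid, l in design.levels.items() if l == lev]
        dev = b[cols].to_numpy(dtype=float) - lev
        out[lev] = float(np.nanmedian(dev))
    return pd.Series(out, name="median_deviation").rename_axis("level")


def _paired_onesided(after, before, better: str) -> float:
    """One-sided paired t-test that `after` is better than `before`."""
    after = np.asarray(after, float)
    before = np.asarray(before, float)
    if after.size < 2:
        return np.nan
    if np.allclose(after, before):
        return np.nan
    alt = "greater" if better == "higher" else "less"
    return float(stats.ttest_rel(after, before, alternative=alt).pvalue)


def compare_methods(
    raw_betas,
    corrected_betas_by_method: dict,
    duplicates: DuplicateDesign | None = None,
    titration=None,
    titration_design: TitrationDesign | None = None,
) -> pd.DataFrame:
    """Tabulate duplicate-concordance and titration-accuracy metrics.

    One row per method (``raw`` first).  Duplicate metrics are means over
    per-pair values with one-sided paired t-tests against raw (higher
    correlation / lower difference is better); titration columns give the
    per-level median deviations plus their mean absolute value.
    ``titration``, when given, maps method name to the beta matrix of the
    titration samples (``raw`` key for uncorrected).
    """
    methods = ["raw"] + list(corrected_betas_by_method)
    betas = {"raw": raw_betas, **corrected_betas_by_method}
    rows = []
    per_pair = {}
    for name in methods:
        row: dict = {"method": name}
        if duplicates is not None:
            b = betas[name]
            if len(duplicates.pairs) < 2:
                warnings.warn("fewer than 2 duplicate pairs; t-tests omitted")
            cors = [mean_centered_correlation(b, p) for p in duplicates.pairs]
            diffs = [mean_abs_beta_diff(b, p) for p in duplicates.pairs]
            per_pair[name] = (cors, diffs)
            row["mean_centered_correlation"] = float(np.mean(cors))
            row["mean_abs_diff_pct"] = float(np.mean(diffs))
            if name != "raw" and len(duplicates.pairs) >= 2:
                row["p_correlation_vs_raw"] = _paired_onesided(
                    cors, per_pair["raw"][0], "higher")
                row["p_diff_vs_raw"] = _paired_onesided(
                    diffs, per_pair["raw"][1], "lower")
        if titration is not None and titration_design is not None and name in titration:
            dev = titration_deviation(titration[name], titration_design)
            for lev, v in dev.items():
                row[f"dev_at_{lev:g}"] = v
            row["mean_abs_deviation"] = float(dev.abs().mean())
        rows.append(row)
    return pd.DataFrame(rows).set_index("method")
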