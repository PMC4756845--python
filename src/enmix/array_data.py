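"""Data model, text I/O, QC and summaries for Infinium-style intensity data.

The in-memory containers are thin wrappers over pandas objects:

* :class:`ProbeManifest` — probe id, design type (I/II), colour channel
  (type I only), optional chromosome;
* :class:`IntensitySet` — methylated/unmethylated intensity matrices
  (probes x samples), out-of-band intensities for type I probes, the
  internal-control table, optional bead counts;
* :class:`BetaMatrix` — methylation fractions ``M / (M + U + offset)``.

All native formats are delimited text (TSV/CSV): one matrix per file with
sample ids as header and probe ids in the first column.  IDAT-level
parsing is out of scope; an external adapter can construct
:class:`IntensitySet` directly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ProbeManifest",
    "IntensitySet",
    "BetaMatrix",
    "SixPartSplit",
    "PART_NAMES",
    "read_intensity_tables",
    "write_intensity_tables",
    "split_six_parts",
    "compute_beta",
    "detection_pvalue",
    "qc_filter",
    "nmode",
    "frequency_polygon",
]

#: the six intensity parts, each modelled and corrected separately:
#: Infinium I probes contribute M and U on their assigned channel;
#: Infinium II probes read M on green and U on red.
PART_NAMES = (
    "I-red-M",
    "I-red-U",
    "I-green-M",
    "I-green-U",
    "II-green-M",
    "II-red-U",
)

#: measurement colour channel of each part
PART_CHANNEL = {
    "I-red-M": "red",
    "I-red-U": "red",
    "I-green-M": "green",
    "I-green-U": "green",
    "II-green-M": "green",
    "II-red-U": "red",
}

CONTROL_TYPES = ("negative", "nonpolymorphic_red", "nonpolymorphic_green", "other")


@dataclass
class ProbeManifest:
    """Probe annotation driving the six-part split.

    ``table`` columns: ``probe_id``, ``design_type`` ("I"/"II"),
    ``channel`` ("red"/"green" for type I, empty for type II) and an
    optional ``chromosome``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"probe_id", "design_type", "channel"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        if t["probe_id"].duplicated().any():
            dups = t.loc[t["probe_id"].duplicated(), "probe_id"].tolist()[:5]
            raise ValueError(f"duplicate probe ids in manifest: {dups} ...")
        bad_type = ~t["design_type"].isin(["I", "II"])
        if bad_type.any():
            raise ValueError("design_type must be 'I' or 'II'")
        is_one = t["design_type"] == "I"
        chan = t["channel"].where(t["channel"].notna(), "")
        if (~chan[is_one].isin(["red", "green"])).any():
            raise ValueError("every type I probe needs channel 'red' or 'green'")
        if (chan[~is_one] != "").any():
            raise ValueError("type II probes must not carry a channel")
        self.table = t.reset_index(drop=True)

    @property
    def probe_ids(self) -> pd.Index:
        return pd.Index(self.table["probe_id"]).rename(None)

    def ids_of(self, design_type: str, channel: str | None = None) -> pd.Index:
        t = self.table
        m = t["design_type"] == design_type
        if channel is not None:
            m &= t["channel"] == channel
        return pd.Index(t.loc[m, "probe_id"]).rename(None)

    @classmethod
    def read_csv(cls, path) -> "ProbeManifest":
        t = pd.read_csv(path, dtype={"probe_id": str, "design_type": str, "channel": str})
        t["channel"] = t["channel"].fillna("")
        return cls(t)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class IntensitySet:
    """Raw (or corrected) intensities for a set of samples.

    ``M``/``U`` are probes x samples frames aligned to the manifest.
    ``oob_M``/``oob_U`` hold the out-of-band readings for exactly the
    type I probes.  ``controls`` is a long table with columns
    ``sample_id, control_type, red, green``.
    """

    M: pd.DataFrame
    U: pd.DataFrame
    oob_M: pd.DataFrame | None = None
    oob_U: pd.DataFrame | None = None
    controls: pd.DataFrame | None = None
    bead_count_M: pd.DataFrame | None = None
    bead_count_U: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.M.index.equals(self.U.index) or not self.M.columns.equals(self.U.columns):
            raise ValueError("M and U must share probe order and sample ids")
        for name in ("M", "U", "oob_M", "oob_U"):
            df = getattr(self, name)
            if df is not None and (df.to_numpy() < 0).any():
                r, c = np.argwhere(df.to_numpy() < 0)[0]
                raise ValueError(
                    f"negative intensity in {name} at probe {df.index[r]!r}, sample {df.columns[c]!r}"
                )
        if self.controls is not None:
            need = {"sample_id", "control_type", "red", "green"}
            if not need <= set(self.controls.columns):
                raise ValueError(f"controls table needs columns {sorted(need)}")

    @property
    def samples(self) -> list:
        return list(self.M.columns)

    @property
    def probe_ids(self) -> pd.Index:
        return self.M.index

    def negative_controls(self, sample_id, channel: str) -> np.ndarray:
        if self.controls is None:
            raise ValueError("no control-probe table attached")
        t = self.controls
        rows = t[(t["sample_id"] == sample_id) & (t["control_type"] == "negative")]
        if rows.empty:
            raise ValueError(f"no negative controls for sample {sample_id!r}")
        return rows[channel].to_numpy(dtype=float)

    def nonpolymorphic_controls(self, sample_id, channel: str) -> np.ndarray:
        """Intensities of the non-polymorphic controls *targeting* ``channel``."""
        if self.controls is None:
            raise ValueError("no control-probe table attached")
        t = self.controls
        rows = t[(t["sample_id"] == sample_id) & (t["control_type"] == f"nonpolymorphic_{channel}")]
        if rows.empty:
            raise ValueError(f"no non-polymorphic ({channel}) controls for sample {sample_id!r}")
        return rows[channel].to_numpy(dtype=float)

    def copy(self) -> "IntensitySet":
        return IntensitySet(
            M=self.M.copy(),
            U=self.U.copy(),
            oob_M=None if self.oob_M is None else self.oob_M.copy(),
            oob_U=None if self.oob_U is None else self.oob_U.copy(),
            controls=None if self.controls is None else self.controls.copy(),
            bead_count_M=None if self.bead_count_M is None else self.bead_count_M.copy(),
            bead_count_U=None if self.bead_count_U is None else self.bead_count_U.copy(),
        )


@dataclass
class BetaMatrix:
    """Per-sample, per-CpG methylation fractions in [0, 1)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        finite = v[np.isfinite(v)]
        if finite.size and ((finite < 0).any() or (finite >= 1).any()):
            raise ValueError("beta values must lie in [0, 1)")

    @property
    def samples(self) -> list:
        return list(self.values.columns)


@dataclass
class SixPartSplit:
    """The six-part partition of all M/U measurements of an IntensitySet."""

    parts: dict = field(default_factory=dict)  # part name -> probes x samples frame

    def __post_init__(self) -> None:
        unknown = set(self.parts) - set(PART_NAMES)
        if unknown:
            raise ValueError(f"unknown part names: {sorted(unknown)}")

    def n_elements(self) -> int:
        return int(sum(df.size for df in self.parts.values()))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_matrix(path, what: str) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0,
                     float_precision="round_trip").astype(float)
    df.index = df.index.astype(str)
    df.index.name = None
    arr = df.to_numpy()
    if (arr < 0).any():
        r, c = np.argwhere(arr < 0)[0]
        raise ValueError(
            f"{what}: negative entry at probe {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    return df


def read_intensity_tables(paths: dict, manifest: ProbeManifest) -> IntensitySet:
    """Load an IntensitySet from delimited text tables.

    ``paths`` maps field names (``M``, ``U``, optional ``oob_M``,
    ``oob_U``, ``controls``, ``bead_count_M``, ``bead_count_U``) to file
    paths.  Probe ids are reconciled against the manifest; offenders are
    listed in the error.
    """
    if "M" not in paths or "U" not in paths:
        raise ValueError("need at least 'M' and 'U' tables")
    M = _read_matrix(paths["M"], "M")
    U = _read_matrix(paths["U"], "U")
    want = manifest.probe_ids
    for name, df in (("M", M), ("U", U)):
        extra = df.index.difference(want)
        miss = want.difference(df.index)
        if len(extra) or len(miss):
            raise ValueError(
                f"{name} probes disagree with manifest; "
                f"unknown={list(extra[:5])} missing={list(miss[:5])}"
            )
    M = M.loc[want]
    U = U.loc[want]

    kw: dict = {}
    type1 = manifest.ids_of("I")
    for name in ("oob_M", "oob_U"):
        if name in paths and paths[name] is not None:
            df = _read_matrix(paths[name], name)
            if set(df.index) != set(type1):
                raise ValueError(f"{name} must cover exactly the type I probes")
            kw[name] = df.loc[type1]
    if paths.get("controls") is not None:
        sep = "\t" if str(paths["controls"]).endswith((".tsv", ".txt")) else ","
        kw["controls"] = pd.read_csv(paths["controls"], sep=sep,
                                     float_precision="round_trip")
    for name in ("bead_count_M", "bead_count_U"):
        if paths.get(name) is not None:
            kw[name] = _read_matrix(paths[name], name).loc[want]
    return IntensitySet(M=M, U=U, **kw)


def write_intensity_tables(x: IntensitySet, outdir, *, sep: str = "\t") -> dict:
    """Write every present field of ``x`` as a delimited text table.

    Returns the mapping of field name to file path, suitable for
    :func:`read_intensity_tables`.  Full float precision is kept so a
    round trip is value-identical.
    """
    os.makedirs(outdir, exist_ok=True)
    ext = "tsv" if sep == "\t" else "csv"
    paths = {}
    for name in ("M", "U", "oob_M", "oob_U", "bead_count_M", "bead_count_U"):
        df = getattr(x, name)
        if df is not None:
            p = os.path.join(outdir, f"{name}.{ext}")
            df.to_csv(p, sep=sep, index_label="probe_id", float_format="%.17g")
            paths[name] = p
    if x.controls is not None:
        p = os.path.join(outdir, f"controls.{ext}")
        x.controls.to_csv(p, sep=sep, index=False, float_format="%.17g")
        paths["controls"] = p
    return paths


# ---------------------------------------------------------------------------
# the six-part split
# ---------------------------------------------------------------------------

def split_six_parts(x: IntensitySet, manifest: ProbeManifest) -> SixPartSplit:
    """Partition all M/U measurements into the six design x channel parts.

    Every measurement lands in exactly one part, so the total element
    count is ``2 * n_probes * n_samples``.
    """
    if not x.probe_ids.equals(manifest.probe_ids):
        raise ValueError("intensity probes must match the manifest (same order)")
    i_red = manifest.ids_of("I", "red")
    i_green = manifest.ids_of("I", "green")
    type2 = manifest.ids_of("II")
    parts = {
        "I-red-M": x.M.loc[i_red],
        "I-red-U": x.U.loc[i_red],
        "I-green-M": x.M.loc[i_green],
        "I-green-U": x.U.loc[i_green],
        "II-green-M": x.M.loc[type2],
        "II-red-U": x.U.loc[type2],
    }
    return SixPartSplit(parts=parts)


# ---------------------------------------------------------------------------
# beta values, detection p-values, QC
# ---------------------------------------------------------------------------

def compute_beta(M, U, offset: float = 100.0):
    """Methylation fraction M / (M + U + offset), in [0, 1).

    The constant offset regularises the ratio when both intensities are
    small; with the default 100, M=100/U=0 gives exactly 0.5 and
    M=U=0 gives 0.
    """
    M = np.asarray(M, dtype=float)
    U = np.asarray(U, dtype=float)
    if (M < 0).any() or (U < 0).any():
        raise ValueError("intensities must be non-negative")
    return M / (M + U + offset)


def detection_pvalue(x: IntensitySet, manifest: ProbeManifest) -> pd.DataFrame:
    """Empirical detection p-value per probe and sample.

    p = (#{negative-control sums >= M+U} + 1) / (n + 1) against the
    empirical distribution of summed negative-control intensities matched
    to the probe's chemistry: a type I probe sums two values from its
    assigned channel, a type II probe one green plus one red value
    (controls paired in table order).  The +1 convention avoids exact
    zeros; p is monotone non-increasing in M+U.
    """
    if x.controls is None:
        raise ValueError("detection p-values need the negative-control table")
    total = x.M.to_numpy(dtype=float) + x.U.to_numpy(dtype=float)
    out = np.empty_like(total)

    is_one = (manifest.table["design_type"] == "I").to_numpy()
    for j, sample in enumerate(x.samples):
        red = x.negative_controls(sample, "red")
        green = x.negative_controls(sample, "green")
        n = min(red.size, green.size)
        sums = {
            "red": np.sort(2.0 * red),
            "green": np.sort(2.0 * green),
            "both": np.sort(red[:n] + green[:n]),
        }
        chan = manifest.table["channel"].to_numpy()
        for key, mask in (
            ("red", is_one & (chan == "red")),
            ("green", is_one & (chan == "green")),
            ("both", ~is_one),
        ):
            ref = sums[key]
            # number of control sums >= observed
            ge = ref.size - np.searchsorted(ref, total[mask, j], side="left")
            out[mask, j] = (ge + 1.0) / (ref.size + 1.0)
    return pd.DataFrame(out, index=x.probe_ids, columns=x.samples)


def qc_filter(
    x: IntensitySet,
    detection_p: pd.DataFrame,
    p_threshold: float = 0.05,
    bead_threshold: int = 3,
) -> pd.DataFrame:
    """Boolean exclusion mask (True = drop the measurement).

    A measurement is excluded iff either bead count is strictly below
    ``bead_threshold`` or the detection p-value is strictly above
    ``p_threshold``; absent bead counts skip the bead rule.
    """
    if not detection_p.index.equals(x.probe_ids) or list(detection_p.columns) != x.samples:
        raise ValueError("detection_p shape/order must match the intensity set")
    mask = detection_p.to_numpy() > p_threshold
    for bc in (x.bead_count_M, x.bead_count_U):
        if bc is not None:
            if bc.shape != x.M.shape:
                raise ValueError("bead-count shape must match the intensity matrices")
            mask |= bc.to_numpy() < bead_threshold
    return pd.DataFrame(mask, index=x.probe_ids, columns=x.samples)


# ---------------------------------------------------------------------------
# distribution summaries
# ---------------------------------------------------------------------------

def nmode(
    betas_per_cpg,
    n_bins: int = 20,
    min_peak_frac: float = 0.05,
    valley_frac: float = 0.5,
) -> int:
    """Number of modes of a CpG's beta distribution across samples.

    Counts local maxima of a fixed 20-bin histogram on [0, 1]; a peak
    must carry more than ``min_peak_frac`` of the samples, and two peaks
    are distinct only if the valley between them drops below
    ``valley_frac`` of the smaller peak.  CpGs with more than one mode
    typically flag polymorphisms under the probe.
    """
    v = np.asarray(betas_per_cpg, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 20:
        raise ValueError(f"nmode needs at least 20 samples, got {v.size}")
    counts, _ = np.histogram(v, bins=n_bins, range=(0.0, 1.0))
    # local maxima (plateaus count once, at their left edge)
    padded = np.concatenate([[-1], counts, [-1]])
    peaks = []
    i = 1
    while i <= n_bins:
        j = i
        while j < n_bins and padded[j + 1] == padded[i]:
            j += 1
        if padded[i] > padded[i - 1] and padded[i] > padded[j + 1]:
            peaks.append((i - 1, counts[i - 1]))
        i = j + 1
    peaks = [(idx, h) for idx, h in peaks if h > min_peak_frac * v.size]
    if not peaks:
        return 1
    accepted = [peaks[0]]
    for idx, h in peaks[1:]:
        prev_idx, prev_h = accepted[-1]
        valley = counts[prev_idx + 1 : idx].min() if idx > prev_idx + 1 else min(h, prev_h)
        if valley < valley_frac * min(h, prev_h):
            accepted.append((idx, h))
        elif h > prev_h:  # merged: keep the taller representative
            accepted[-1] = (idx, h)
    return len(accepted)


def frequency_polygon(values, n_bins: int, value_range: tuple | None = None):
    """Histogram counts at bin midpoints (the frequency-polygon summary).

    Returns ``(midpoints, counts)``; counts sum to the number of finite
    values.  Deterministic given identical input.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    counts, edges = np.histogram(v, bins=n_bins, range=value_range)
    midpoints = 0.5 * (edges[:-1] + edges[1:])
    return midpoints, counts
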