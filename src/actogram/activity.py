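"""Activity indices: per-frame A, per-bin A0/A1 and M0/M1/M2, smoothing.

The per-frame activity index ``A`` is the percentage of counted pixels
flagged as changed in the cleaned binary mask; it ranges from 0 to 100 and
is reported at 0.01 resolution (full precision is kept internally).  The
manual observer score ``M`` is an ordinal 0-3 rating of how many animals
move.  Both are aggregated into per-bin exceedance fractions:

* ``A0`` / ``A1`` — fraction of frames in the bin with ``A > 0`` / ``A > 0.01``
* ``M0`` / ``M1`` / ``M2`` — fraction of seconds with ``M > 0`` / ``> 1`` / ``> 2``

All threshold predicates are strict.  The default bin width is one minute;
a 600 s bin gives the 10-minute resolution used for long-term monitoring.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ActivitySeries",
    "ManualScoreSeries",
    "AggregateSeries",
    "compute_A",
    "aggregate",
    "moving_average",
    "A_THRESHOLDS",
    "M_THRESHOLDS",
]

#: Default exceedance thresholds: A > 0 and A > 0.01 (percent scale).
A_THRESHOLDS = (0.0, 0.01)
#: Default exceedance thresholds for the ordinal manual score.
M_THRESHOLDS = (0, 1, 2)


@dataclasses.dataclass
class ActivitySeries:
    """Per-frame automatic activity index, percent scale, in [0, 100]."""

    timestamps: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps.shape != self.values.shape:
            raise ValueError("timestamps and values differ in length")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 100):
            raise ValueError("A index must lie in [0, 100]")

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"timestamp": self.timestamps, "A": self.values})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ActivitySeries":
        df = pd.read_csv(path)
        return cls(df["timestamp"].to_numpy(), df["A"].to_numpy())


@dataclasses.dataclass
class ManualScoreSeries:
    """Observer scores at 1 s resolution, integer 0-3."""

    timestamps: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values)
        if self.timestamps.shape != self.values.shape:
            raise ValueError("timestamps and values differ in length")
        if not np.isin(self.values, (0, 1, 2, 3)).all():
            raise ValueError("M scores must be integers in {0, 1, 2, 3}")
        self.values = self.values.astype(int)

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"timestamp": self.timestamps, "M": self.values})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ManualScoreSeries":
        df = pd.read_csv(path)
        return cls(df["timestamp"].to_numpy(), df["M"].to_numpy())


@dataclasses.dataclass
class AggregateSeries:
    """Per-bin exceedance fractions (A0/A1 or M0/M1/M2), each in [0, 1].

    Only bins containing samples are present; an empty bin is missing, not
    zero.  ``n`` is the per-bin sample count; the trailing bin may be
    partial (``partial_last``).
    """

    bin_start: np.ndarray
    bin_width: float
    values: dict[str, np.ndarray]
    n: np.ndarray
    partial_last: bool = False

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"bin_start": self.bin_start})
        for name, v in self.values.items():
            df[name] = v
        df["n"] = self.n
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, bin_width: float | None = None) -> "AggregateSeries":
        df = pd.read_csv(path)
        bs = df["bin_start"].to_numpy(float)
        if bin_width is None:
            if len(bs) < 2:
                raise ValueError("cannot infer bin_width from a single bin")
            bin_width = float(np.min(np.diff(bs)))
        cols = [c for c in df.columns if c not in ("bin_start", "n")]
        n = df["n"].to_numpy(int) if "n" in df else np.ones(len(df), int)
        return cls(bs, bin_width, {c: df[c].to_numpy(float) for c in cols}, n)

    def column(self, name: str) -> np.ndarray:
        return self.values[name]


def compute_A(mask: np.ndarray, counted_pixels: int) -> float:
    """Percentage of counted pixels that are white in a cleaned binary mask.

    ``counted_pixels`` is the frame area minus the excluded-pixel count;
    it must be positive.  Full precision is returned — rounding to the 0.01
    reporting resolution happens only at output time.
    """
    if counted_pixels <= 0:
        raise ValueError("counted_pixels must be positive")
    mask = np.asarray(mask)
    return 100.0 * float(mask.sum()) / float(counted_pixels)


def _default_thresholds(series) -> tuple[Sequence[float], Sequence[str]]:
    if isinstance(series, ManualScoreSeries):
        return M_THRESHOLDS, [f"M{i}" for i in range(len(M_THRESHOLDS))]
    return A_THRESHOLDS, [f"A{i}" for i in range(len(A_THRESHOLDS))]


def aggregate(
    series: ActivitySeries | ManualScoreSeries,
    bin_width: float = 60.0,
    thresholds: Sequence[float] | None = None,
    labels: Sequence[str] | None = None,
    epoch: float = 0.0,
) -> AggregateSeries:
    """Bin a series and compute per-bin strict-exceedance fractions.

    Bins are aligned to integer multiples of ``bin_width`` from ``epoch``.
    For each threshold ``t`` the fraction of in-bin samples with value
    strictly greater than ``t`` is reported.  Defaults: thresholds (0, 0.01)
    labelled A0/A1 for activity series, (0, 1, 2) labelled M0/M1/M2 for
    manual scores.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if len(series) == 0:
        raise ValueError("empty series")
    if thresholds is None:
        thresholds, default_labels = _default_thresholds(series)
        labels = labels or default_labels
    elif labels is None:
        prefix = "M" if isinstance(series, ManualScoreSeries) else "A"
        labels = [f"{prefix}{i}" for i in range(len(thresholds))]
    if len(labels) != len(thresholds):
        raise ValueError("labels and thresholds differ in length")

    t = np.asarray(series.timestamps, dtype=float)
    v = np.asarray(series.values, dtype=float)
    bins = np.floor((t - epoch) / bin_width).astype(np.int64)
    uniq, inv = np.unique(bins, return_inverse=True)
    n = np.bincount(inv)
    values = {}
    for thr, name in zip(thresholds, labels):
        exceed = np.bincount(inv, weights=(v > thr).astype(float))
        values[name] = exceed / n
    bin_start = epoch + uniq * bin_width
    # a trailing bin whose samples stop short of its end is flagged partial
    dt = float(np.median(np.diff(t))) if len(t) > 1 else bin_width
    partial_last = bool(t.max() + dt < bin_start[-1] + bin_width - 1e-9)
    return AggregateSeries(bin_start, float(bin_width), values, n, partial_last)


def moving_average(values: np.ndarray, width: int) -> np.ndarray:
    """Centred simple moving average with an odd window.

    Near the ends the window shrinks symmetrically to what is available, so
    the output has the input's length and preserves its global min/max
    bounds.  An 11-sample window on a 1 s series is the 11 s smoothing used
    for display.
    """
    if width < 1 or width % 2 == 0:
        raise ValueError("width must be odd and >= 1")
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n == 0:
        return v.copy()
    h = width // 2
    idx = np.arange(n)
    half = np.minimum(h, np.minimum(idx, n - 1 - idx))
    cs = np.concatenate(([0.0], np.cumsum(v)))
    lo = idx - half
    hi = idx + half + 1
    return (cs[hi] - cs[lo]) / (hi - lo)
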