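"""Long-term activity summaries and deviation flagging.

Two consumers of the aggregated indices:

* :func:`daily_summary` — per-day mean +/- SEM of A0/A1 over the daytime
  window (default 6:30-18:30), the long-term welfare-monitoring table.
* :class:`DailyProfile` — a per-bin-of-day baseline (median and MAD of the
  index across reference days on a 10-minute grid) from which
  :func:`detect_anomalies` flags bins that deviate by more than ``k`` MADs.
  Activity bins are zero-inflated at night, so the robust median/MAD pair
  is used instead of mean/SD; ``mad_floor`` keeps the tolerance band from
  collapsing where the baseline is exactly constant (e.g. all-zero nights).

The detector is an extension beyond the published pipeline: the study
proposes abnormal-activity detection (illness, birth events) but does not
specify a rule.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .activity import AggregateSeries

__all__ = ["DailyProfile", "daily_summary", "detect_anomalies",
           "DEFAULT_DAY_WINDOW"]

#: Daytime window in seconds of day: 6:30 to 18:30.
DEFAULT_DAY_WINDOW = (6.5 * 3600.0, 18.5 * 3600.0)


def daily_summary(
    agg: AggregateSeries,
    day_window: tuple[float, float] = DEFAULT_DAY_WINDOW,
    day_length: float = 86400.0,
) -> pd.DataFrame:
    """Per-day mean +/- SEM of every index column over the daytime window.

    ``day_length`` supports compressed synthetic days.  Bin order is
    irrelevant; a day appears only if it has at least one in-window bin.
    """
    start, end = day_window
    if not (0 <= start < end <= day_length):
        raise ValueError("empty or invalid day window")
    df = agg.to_frame()
    tod = np.mod(df["bin_start"].to_numpy(float), day_length)
    in_window = (tod >= start) & (tod < end)
    df = df[in_window]
    if df.empty:
        raise ValueError("no bins inside the day window")
    day = np.floor(df["bin_start"].to_numpy(float) / day_length).astype(np.int64)
    df = df.assign(day=day)
    cols = [c for c in df.columns if c not in ("bin_start", "n", "day")]
    out = {}
    g = df.groupby("day")
    for c in cols:
        out[f"{c}_mean"] = g[c].mean()
        # SEM with sample sd; a single bin gives SEM 0
        out[f"{c}_sem"] = g[c].apply(
            lambda v: float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
        )
    out["n_bins"] = g.size()
    return pd.DataFrame(out)


@dataclasses.dataclass
class DailyProfile:
    """Baseline daily activity profile on a fixed bin-of-day grid.

    Construct, then :meth:`fit` on an aggregate series spanning >= 2
    reference days; the baseline (median, MAD across days) is defined only
    for grid bins observed on at least two days.
    """

    grid_s: float = 600.0
    day_length: float = 86400.0
    day_window: tuple[float, float] = DEFAULT_DAY_WINDOW
    column: str = "A0"
    median_: np.ndarray | None = dataclasses.field(default=None, repr=False)
    mad_: np.ndarray | None = dataclasses.field(default=None, repr=False)
    n_days_: np.ndarray | None = dataclasses.field(default=None, repr=False)

    @property
    def n_bins(self) -> int:
        return int(np.ceil(self.day_length / self.grid_s))

    def _bin_of_day(self, bin_start: np.ndarray) -> np.ndarray:
        return np.floor(
            np.mod(bin_start, self.day_length) / self.grid_s
        ).astype(np.int64)

    def fit(self, agg: AggregateSeries) -> "DailyProfile":
        """Estimate per-bin median and MAD across the reference days."""
        v = agg.column(self.column)
        bod = self._bin_of_day(np.asarray(agg.bin_start, float))
        nb = self.n_bins
        med = np.full(nb, np.nan)
        mad = np.full(nb, np.nan)
        n_days = np.zeros(nb, dtype=int)
        for b in range(nb):
            vals = v[bod == b]
            n_days[b] = len(vals)
            if len(vals) >= 2:
                m = float(np.median(vals))
                med[b] = m
                mad[b] = float(np.median(np.abs(vals - m)))
        if (n_days >= 2).sum() == 0:
            raise ValueError("need bins observed on at least 2 reference days")
        self.median_, self.mad_, self.n_days_ = med, mad, n_days
        return self

    @property
    def is_fitted(self) -> bool:
        return self.median_ is not None


def detect_anomalies(
    profile: DailyProfile,
    day: AggregateSeries,
    k: float = 5.0,
    mad_floor: float = 0.005,
) -> pd.DataFrame:
    """Flag bins of a test day that deviate from the fitted baseline.

    Bin ``b`` with value ``v`` is flagged iff
    ``|v - median_b| > k * max(MAD_b, mad_floor)``; bins without a defined
    baseline are skipped.  Larger ``k`` can only shrink the flag set;
    ``k = inf`` flags nothing.

    Returns a DataFrame of the flagged bins with columns bin_start, value,
    baseline_median, baseline_mad, deviation.
    """
    if not profile.is_fitted:
        raise ValueError("profile is not fitted")
    v = day.column(profile.column)
    bs = np.asarray(day.bin_start, float)
    bod = profile._bin_of_day(bs)
    med = profile.median_[bod]
    mad = profile.mad_[bod]
    defined = ~np.isnan(med)
    dev = np.abs(v - med)
    tol = k * np.maximum(mad, mad_floor)
    flagged = defined & (dev > tol)
    return pd.DataFrame(
        {
            "bin_start": bs[flagged],
            "value": v[flagged],
            "baseline_median": med[flagged],
            "baseline_mad": mad[flagged],
            "deviation": dev[flagged],
        }
    )
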