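"""Method-agreement statistics between automatic and manual activity series.

The automatic index A is nearly continuous while the observer score M is a
four-level ordinal scale; neither is normally distributed, so agreement is
assessed nonparametrically:

* Spearman rank correlation between paired series (per-second A vs M, and
  per-minute A0/A1 vs M0/M1/M2);
* Kolmogorov-Smirnov normality screening (Lilliefors correction, since the
  normal parameters are estimated from the data);
* Kruskal-Wallis rank ANOVA of A grouped by the M level, followed by
  Dunn's tie-corrected post-hoc z tests for all level pairs;
* group summaries as mean +/- SEM.

Dunn p-values are unadjusted by default (per-pair values are reported as
such in the source protocol); Bonferroni and Holm adjustments are optional.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

from .activity import ActivitySeries, ManualScoreSeries, aggregate

__all__ = [
    "spearman",
    "kruskal_wallis",
    "dunn_posthoc",
    "group_summary",
    "ks_normality",
    "compare",
    "ComparisonReport",
]

ALPHA = 0.05  # conventional significance level used in summaries


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranked ties.

    Returns ``(rs, p)``; p from the t approximation.  A constant input makes
    rs undefined and is reported as ``(nan, nan)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series length mismatch")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p (k-1 df).

    All-identical data carry no rank information; that degenerate case is
    reported as ``(0.0, 1.0)``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need at least 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    adjust: str | None = None,
) -> pd.DataFrame:
    """Dunn's post-hoc test for all group pairs after Kruskal-Wallis.

    For groups i, j with mean ranks Ri, Rj in the pooled ranking of N
    observations,

        z = (Ri - Rj) / sqrt([N(N+1)/12 - T/(12(N-1))] * (1/ni + 1/nj))

    where ``T = sum(t^3 - t)`` over tie groups of size t.  Two-sided normal
    p-values, unadjusted by default; ``adjust`` may be "bonferroni" or
    "holm".

    Returns a DataFrame with columns group_i, group_j, z, p.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need at least 2 non-empty groups")
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    sizes = [len(g) for g in groups]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [
        ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(groups))
    ]
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))

    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
            if se == 0:
                z, p = 0.0, 1.0
            else:
                z = (mean_ranks[i] - mean_ranks[j]) / se
                p = 2.0 * sps.norm.sf(abs(z))
            rows.append((i, j, z, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["group_i", "group_j", "z", "p"])
    if adjust is not None:
        method = {"bonferroni": "bonferroni", "holm": "holm"}[adjust]
        df["p"] = multipletests(df["p"].to_numpy(), method=method)[1]
    return df


def group_summary(groups: Sequence[Sequence[float]]) -> pd.DataFrame:
    """Mean +/- SEM (sd / sqrt(n), sample sd) per group; SEM is 0 for n=1."""
    rows = []
    for i, g in enumerate(groups):
        g = np.asarray(g, dtype=float)
        if len(g) == 0:
            raise ValueError("empty group")
        sem = float(np.std(g, ddof=1) / np.sqrt(len(g))) if len(g) > 1 else 0.0
        rows.append((i, float(np.mean(g)), sem, len(g)))
    return pd.DataFrame(rows, columns=["group", "mean", "sem", "n"])


def ks_normality(x: Sequence[float]) -> tuple[float, float]:
    """Kolmogorov-Smirnov normality test with Lilliefors correction.

    The correction accounts for the normal mean/sd being estimated from the
    sample (the plain KS p-value would be anti-conservative).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0:
        return 0.0, 0.0  # a constant is maximally non-normal in this context
    stat, p = lilliefors(x, dist="norm")
    return float(stat), float(p)


def _per_second(series: ActivitySeries) -> ActivitySeries:
    """Average the per-frame A index within each whole second."""
    sec = np.floor(series.timestamps).astype(np.int64)
    uniq, inv = np.unique(sec, return_inverse=True)
    sums = np.bincount(inv, weights=series.values)
    counts = np.bincount(inv)
    return ActivitySeries(uniq.astype(float), sums / counts)


@dataclasses.dataclass
class ComparisonReport:
    """All agreement statistics between one A series and one M series."""

    spearman_rs: pd.DataFrame  # pair, rs, p  (per-second A~M + minute indices)
    ks_normality: pd.DataFrame  # series, stat, p
    kruskal_wallis: tuple[float, float]  # H, p of A grouped by M level
    dunn: pd.DataFrame  # M-level pairs, z, p
    group_summaries: pd.DataFrame  # per M level: mean, sem, n of A
    alpha: float = ALPHA

    def to_dict(self) -> dict:
        return {
            "spearman": self.spearman_rs.to_dict(orient="records"),
            "ks_normality": self.ks_normality.to_dict(orient="records"),
            "kruskal_wallis": {
                "H": self.kruskal_wallis[0],
                "p": self.kruskal_wallis[1],
            },
            "dunn": self.dunn.to_dict(orient="records"),
            "group_summaries": self.group_summaries.to_dict(orient="records"),
            "alpha": self.alpha,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=float))

    def summary(self) -> str:
        lines = ["Method agreement report", "=" * 23, ""]
        lines.append("Spearman rank correlations:")
        for _, r in self.spearman_rs.iterrows():
            lines.append(f"  {r['pair']:<12} Rs = {r['rs']:+.3f}  (p = {r['p']:.4g})")
        lines.append("")
        lines.append("Normality (KS/Lilliefors):")
        for _, r in self.ks_normality.iterrows():
            verdict = "non-normal" if r["p"] < self.alpha else "consistent with normal"
            lines.append(
                f"  {r['series']:<12} D = {r['stat']:.4f}  p = {r['p']:.4g}  ({verdict})"
            )
        h, p = self.kruskal_wallis
        lines.append("")
        lines.append(f"Kruskal-Wallis (A by M level): H = {h:.3f}, p = {p:.4g}")
        lines.append("Dunn post-hoc (unadjusted):")
        for _, r in self.dunn.iterrows():
            mark = "*" if r["p"] < self.alpha else " "
            lines.append(
                f"  M={int(r['group_i'])} vs M={int(r['group_j'])}: "
                f"z = {r['z']:+.3f}, p = {r['p']:.4g} {mark}"
            )
        lines.append("")
        lines.append("A index by M level (mean +/- SEM):")
        for _, r in self.group_summaries.iterrows():
            lines.append(
                f"  M={int(r['group'])}: {r['mean']:.4f} +/- {r['sem']:.4f}  (n={int(r['n'])})"
            )
        return "\n".join(lines)


def compare(
    a_series: ActivitySeries,
    m_series: ManualScoreSeries,
    bin_width: float = 60.0,
) -> ComparisonReport:
    """Full agreement analysis between an automatic A series and manual M
    scores covering the same clock.

    The A series is first averaged to the M series' 1 s resolution for the
    paired statistics; per-minute exceedance indices (A0/A1 vs M0/M1/M2) are
    correlated pair by pair.
    """
    a_sec = _per_second(a_series)
    df = pd.merge(
        a_sec.to_frame(), m_series.to_frame(), on="timestamp", how="inner"
    )
    if len(df) < 3:
        raise ValueError("series overlap too short to compare")
    a, m = df["A"].to_numpy(), df["M"].to_numpy()

    pairs = [("A~M", a, m)]
    agg_a = aggregate(a_series, bin_width=bin_width)
    agg_m = aggregate(m_series, bin_width=bin_width)
    merged = pd.merge(
        agg_a.to_frame(), agg_m.to_frame(), on="bin_start", how="inner",
        suffixes=("_a", "_m"),
    )
    for an in ("A0", "A1"):
        for mn in ("M0", "M1", "M2"):
            if len(merged) >= 3:
                pairs.append(
                    (f"{an}~{mn}", merged[an].to_numpy(), merged[mn].to_numpy())
                )
    sp_rows = []
    for name, xa, xm in pairs:
        rs, p = spearman(xa, xm)
        sp_rows.append((name, rs, p))
    sp = pd.DataFrame(sp_rows, columns=["pair", "rs", "p"])

    ks_rows = []
    for name, x in (("A_per_sec", a), ("M", m.astype(float))):
        try:
            stat, p = ks_normality(x)
        except ValueError:
            stat, p = float("nan"), float("nan")
        ks_rows.append((name, stat, p))
    ks = pd.DataFrame(ks_rows, columns=["series", "stat", "p"])

    levels = sorted(np.unique(m))
    groups = [a[m == lv] for lv in levels]
    if len(groups) >= 2:
        kw = kruskal_wallis(groups)
        dunn = dunn_posthoc(groups)
        dunn["group_i"] = [levels[int(i)] for i in dunn["group_i"]]
        dunn["group_j"] = [levels[int(j)] for j in dunn["group_j"]]
    else:
        kw = (float("nan"), float("nan"))
        dunn = pd.DataFrame(columns=["group_i", "group_j", "z", "p"])
    gs = group_summary(groups)
    gs["group"] = [levels[int(g)] for g in gs["group"]]
    return ComparisonReport(sp, ks, kw, dunn, gs)
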