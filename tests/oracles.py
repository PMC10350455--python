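"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a pipeline quantity by the most direct route
possible (explicit loops, textbook formulas) without sharing code with the
implementation under test.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import chi2, norm

# Active offsets (dy, dx) of the 5x5 rasterised ellipse, anchor (2, 2):
# full middle three rows plus the centre cell of the top and bottom rows.
ELLIPSE_OFFSETS = [
    (-2, 0),
    (-1, -2), (-1, -1), (-1, 0), (-1, 1), (-1, 2),
    (0, -2), (0, -1), (0, 0), (0, 1), (0, 2),
    (1, -2), (1, -1), (1, 0), (1, 1), (1, 2),
    (2, 0),
]


def erode_oracle(mask: np.ndarray) -> np.ndarray:
    """Erosion as an explicit min-filter; out-of-image treated as 1."""
    mask = np.asarray(mask).astype(np.uint8)
    h, w = mask.shape
    out = np.zeros_like(mask)
    for i in range(h):
        for j in range(w):
            val = 1
            for dy, dx in ELLIPSE_OFFSETS:
                y, x = i + dy, j + dx
                if 0 <= y < h and 0 <= x < w:
                    if mask[y, x] == 0:
                        val = 0
                        break
            out[i, j] = val
    return out


def window_masks_oracle(
    stack: np.ndarray, history: int = 28, threshold: float = 20.0,
    variance_floor: float = 4.0,
) -> list[np.ndarray]:
    """Recompute window-mode change masks directly per frame.

    For frame i >= history: population mean/variance over the preceding
    ``history`` frames, floored variance, SMD thresholding.  No incremental
    state is carried, unlike the implementation.
    """
    stack = np.asarray(stack, dtype=np.float64)
    masks = []
    for i in range(history, len(stack)):
        win = stack[i - history : i]
        mean = win.mean(axis=0)
        var = np.maximum(win.var(axis=0), variance_floor)
        smd = (stack[i] - mean) ** 2 / var
        masks.append((smd >= threshold).astype(np.uint8))
    return masks


def window_masks_loops(
    stack: np.ndarray, history: int, threshold: float, variance_floor: float
) -> list[np.ndarray]:
    """Fully scalar triple-loop variant for tiny inputs."""
    t, h, w = stack.shape
    masks = []
    for i in range(history, t):
        m = np.zeros((h, w), dtype=np.uint8)
        for y in range(h):
            for x in range(w):
                vals = [float(stack[k, y, x]) for k in range(i - history, i)]
                mu = sum(vals) / history
                var = sum((v - mu) ** 2 for v in vals) / history
                var = max(var, variance_floor)
                if (float(stack[i, y, x]) - mu) ** 2 / var >= threshold:
                    m[y, x] = 1
        masks.append(m)
    return masks


def _ranks_loop(values: np.ndarray) -> np.ndarray:
    """Mid-ranks computed by counting, not sorting."""
    values = np.asarray(values, dtype=float)
    out = np.empty(len(values))
    for i, v in enumerate(values):
        less = int(np.sum(values < v))
        equal = int(np.sum(values == v))
        out[i] = less + (equal + 1) / 2.0
    return out


def kruskal_brute(groups) -> tuple[float, float]:
    """Kruskal-Wallis H from the textbook formula with tie correction."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    n_total = len(pooled)
    ranks = _ranks_loop(pooled)
    h_stat = 0.0
    start = 0
    for g in groups:
        n = len(g)
        r_sum = ranks[start : start + n].sum()
        h_stat += r_sum * r_sum / n
        start += n
    h_stat = 12.0 / (n_total * (n_total + 1)) * h_stat - 3 * (n_total + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - float(np.sum(counts**3 - counts)) / (n_total**3 - n_total)
    if tie > 0:
        h_stat /= tie
    p = float(chi2.sf(h_stat, len(groups) - 1))
    return float(h_stat), p


def dunn_brute(groups) -> dict[tuple[int, int], tuple[float, float]]:
    """Dunn z and two-sided p per pair, with explicit rank bookkeeping."""
    arrays = [np.asarray(g, float) for g in groups]
    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    ranks = _ranks_loop(pooled)
    mean_ranks, sizes, start = [], [], 0
    for g in arrays:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        sizes.append(len(g))
        start += len(g)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    out = {}
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(base * (1 / sizes[i] + 1 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            out[(i, j)] = (float(z), float(min(1.0, 2 * norm.sf(abs(z)))))
    return out
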