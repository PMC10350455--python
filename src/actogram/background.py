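"""Per-pixel statistical background model with a squared-Mahalanobis test.

Each incoming grayscale frame is compared pixel-by-pixel against a model of
the ``N`` preceding frames (default ``N = 28``, i.e. a 2 s window at 14 Hz).
A pixel is flagged as *changed* when its squared Mahalanobis distance (SMD)
from the background distribution reaches the decision threshold ``T``
(default 20, chosen as a compromise between motion sensitivity and false
signals):

    SMD = (x - mu)^2 / sigma^2        (1-D grayscale case)

Two maintenance strategies are provided:

``window``
    Exact sliding window: mu and sigma^2 are the population mean/variance of
    the previous ``N`` frames.  Fully deterministic and oracle-testable;
    this is the default.
``adaptive``
    Recursive Gaussian-mixture maintenance (learning rate ``1/N``, up to 5
    components per pixel).  Behaves like the common video-surveillance
    background subtractors; masks can differ from window mode on gradually
    changing scenes.

The first ``N`` frames are warm-up: they are absorbed into the model and
their masks carry ``valid=False``.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["BackgroundModel", "ChangeMask", "smd"]


@dataclasses.dataclass
class ChangeMask:
    """Binary change mask for one frame.

    ``valid`` is False during warm-up (the first ``history`` frames), when no
    background distribution exists yet.
    """

    mask: np.ndarray  # H×W uint8, values in {0, 1}
    frame_index: int
    valid: bool

    def white_pixels(self) -> int:
        return int(self.mask.sum())

    def to_image(self) -> np.ndarray:
        """0/255 uint8 rendering for PGM export."""
        return (self.mask * 255).astype(np.uint8)


def smd(x: np.ndarray | float, mean: np.ndarray | float, variance: np.ndarray | float):
    """Squared Mahalanobis distance ``(x - mean)^2 / variance``.

    ``variance`` must already be floored at the model's ``variance_floor``,
    which guarantees a positive denominator.
    """
    d = np.asarray(x, dtype=np.float64) - np.asarray(mean, dtype=np.float64)
    return d * d / np.asarray(variance, dtype=np.float64)


class BackgroundModel:
    """Stateful per-pixel background model; call :meth:`apply` per frame.

    Parameters
    ----------
    history : int
        Number of preceding frames ``N`` in the background model (>= 2).
    threshold : float
        SMD decision threshold ``T``; a pixel with SMD >= T is flagged.
    mode : {"window", "adaptive"}
        Maintenance strategy, see module docstring.
    variance_floor : float
        Minimum variance (intensity² units) used in the SMD denominator;
        prevents division by zero on perfectly static pixels.
    n_components, background_ratio, initial_variance
        Adaptive-mode constants: maximum mixture components per pixel, the
        cumulative-weight fraction designated as background, and the variance
        assigned to a newly created component.
    """

    def __init__(
        self,
        history: int = 28,
        threshold: float = 20.0,
        mode: str = "window",
        variance_floor: float = 4.0,
        n_components: int = 5,
        background_ratio: float = 0.9,
        initial_variance: float = 225.0,
    ) -> None:
        if history < 2:
            raise ValueError("history must be >= 2")
        if threshold <= 0:
            raise ValueError("threshold must be positive")
        if variance_floor <= 0:
            raise ValueError("variance_floor must be positive")
        if mode not in ("window", "adaptive"):
            raise ValueError(f"unknown mode {mode!r}")
        self.history = int(history)
        self.threshold = float(threshold)
        self.mode = mode
        self.variance_floor = float(variance_floor)
        self.n_components = int(n_components)
        self.background_ratio = float(background_ratio)
        self.initial_variance = float(initial_variance)
        self._shape: tuple[int, int] | None = None
        self._frame_index = 0
        # window state
        self._ring: np.ndarray | None = None  # (N, H, W) uint8
        self._ring_pos = 0
        self._n_absorbed = 0
        self._sum: np.ndarray | None = None  # int64
        self._sumsq: np.ndarray | None = None  # int64
        # adaptive state
        self._w: np.ndarray | None = None  # (K, H, W) weights
        self._mu: np.ndarray | None = None
        self._var: np.ndarray | None = None

    # -- shared -----------------------------------------------------------

    def _check_frame(self, frame: np.ndarray) -> np.ndarray:
        frame = np.asarray(frame)
        if frame.ndim != 2:
            raise ValueError("background model expects grayscale HxW frames")
        if self._shape is None:
            self._shape = frame.shape
        elif frame.shape != self._shape:
            raise ValueError(
                f"dimension mismatch: frame {frame.shape} vs model {self._shape}"
            )
        return frame

    def apply(self, frame: np.ndarray) -> ChangeMask:
        """Classify one frame and absorb it into the model."""
        frame = self._check_frame(frame)
        if self.mode == "window":
            return self._apply_window(frame)
        return self._apply_adaptive(frame)

    # -- exact sliding window ---------------------------------------------

    def _apply_window(self, frame: np.ndarray) -> ChangeMask:
        h, w = frame.shape
        n = self.history
        if self._ring is None:
            self._ring = np.zeros((n, h, w), dtype=np.uint8)
            self._sum = np.zeros((h, w), dtype=np.int64)
            self._sumsq = np.zeros((h, w), dtype=np.int64)
        idx = self._frame_index
        self._frame_index += 1

        if self._n_absorbed < n:
            self._push(frame)
            return ChangeMask(np.zeros((h, w), dtype=np.uint8), idx, valid=False)

        # Integer running sums over exactly the N previous frames make the
        # mean/variance exact (no float accumulation drift).
        mean = self._sum / n
        var = self._sumsq / n - mean * mean
        var = np.maximum(var, self.variance_floor)
        d = frame.astype(np.float64) - mean
        mask = (d * d / var >= self.threshold).astype(np.uint8)
        self._push(frame)
        return ChangeMask(mask, idx, valid=True)

    def _push(self, frame: np.ndarray) -> None:
        f8 = frame.astype(np.uint8)
        f64 = frame.astype(np.int64)
        if self._n_absorbed >= self.history:
            old = self._ring[self._ring_pos].astype(np.int64)
            self._sum -= old
            self._sumsq -= old * old
        self._sum += f64
        self._sumsq += f64 * f64
        self._ring[self._ring_pos] = f8
        self._ring_pos = (self._ring_pos + 1) % self.history
        self._n_absorbed += 1

    # -- recursive Gaussian mixture ---------------------------------------

    def _apply_adaptive(self, frame: np.ndarray) -> ChangeMask:
        h, w = frame.shape
        k = self.n_components
        if self._w is None:
            self._w = np.zeros((k, h, w))
            self._mu = np.zeros((k, h, w))
            self._var = np.full((k, h, w), self.initial_variance)
            self._w[0] = 1.0
            self._mu[0] = frame
        idx = self._frame_index
        self._frame_index += 1
        alpha = 1.0 / self.history

        x = frame.astype(np.float64)
        var = np.maximum(self._var, self.variance_floor)
        d2 = (x[None] - self._mu) ** 2 / var
        fits = (d2 < self.threshold) & (self._w > 0)

        # Components ranked by weight/sigma (likely background first); the
        # matched component is the best-ranked fitting one.
        rank = self._w / np.sqrt(var)
        order = np.argsort(-rank, axis=0, kind="stable")
        fits_sorted = np.take_along_axis(fits, order, axis=0)
        first_fit = np.argmax(fits_sorted, axis=0)
        any_fit = fits_sorted.any(axis=0)
        matched = np.take_along_axis(
            order, first_fit[None], axis=0
        )[0]  # component index per pixel (meaningful where any_fit)

        # Background designation: smallest set of top-ranked components whose
        # cumulative weight exceeds background_ratio.
        w_sorted = np.take_along_axis(self._w, order, axis=0)
        cum = np.cumsum(w_sorted, axis=0)
        bg_sorted = (cum - w_sorted) < self.background_ratio
        is_bg = np.zeros_like(fits)
        np.put_along_axis(is_bg, order, bg_sorted, axis=0)

        comp_idx = np.arange(k)[:, None, None]
        match_onehot = (comp_idx == matched[None]) & any_fit[None]

        # weight update: w <- (1-a) w + a * match
        self._w = (1 - alpha) * self._w + alpha * match_onehot
        # matched mean/variance update with rho = alpha
        rho = alpha
        upd = match_onehot
        diff = x[None] - self._mu
        self._mu = np.where(upd, self._mu + rho * diff, self._mu)
        self._var = np.where(upd, self._var + rho * (diff * diff - self._var), self._var)
        self._var = np.maximum(self._var, self.variance_floor)

        # unmatched pixels: replace the weakest component with a new one
        no_fit = ~any_fit
        if np.any(no_fit):
            weakest = np.argmin(self._w, axis=0)
            repl = (comp_idx == weakest[None]) & no_fit[None]
            self._mu = np.where(repl, x[None], self._mu)
            self._var = np.where(repl, self.initial_variance, self._var)
            self._w = np.where(repl, alpha, self._w)
        self._w /= self._w.sum(axis=0, keepdims=True)

        matched_is_bg = np.take_along_axis(is_bg, matched[None], axis=0)[0]
        foreground = no_fit | (any_fit & ~matched_is_bg)
        valid = idx >= self.history
        mask = foreground.astype(np.uint8) if valid else np.zeros((h, w), np.uint8)
        return ChangeMask(mask, idx, valid=valid)
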