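"""Frame-sequence input/output, grayscale conversion and exclusion masking.

The canonical input is a directory of losslessly stored, numbered image
frames (PGM or PNG).  Security-camera overlays (burned-in date/time stamps)
are removed with rectangular exclusion masks before any motion analysis:
an excluded region is set to a constant, so after the background model's
warm-up it can never be flagged as change.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "FrameSequence",
    "ExclusionMask",
    "read_sequence",
    "write_sequence",
    "iter_frames",
    "to_grayscale",
    "apply_exclusion",
    "BT601_COEFFS",
]

#: ITU-R BT.601 luma weights for (R, G, B) — the common video-library choice.
BT601_COEFFS = (0.299, 0.587, 0.114)

_FRAME_EXTENSIONS = (".pgm", ".png", ".ppm")


@dataclasses.dataclass
class FrameSequence:
    """An ordered, uniformly sized stack of 8-bit frames with timestamps.

    Parameters
    ----------
    frames
        List of ``H×W`` (grayscale) or ``H×W×3`` (colour) ``uint8`` arrays,
        all with identical spatial dimensions.
    timestamps
        Seconds since the start of the series, strictly increasing.  When
        built from a directory they are synthesised as ``i / fps``.
    fps
        Nominal frame rate in Hz.
    """

    frames: list[np.ndarray]
    timestamps: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise ValueError("no frames")
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if len(self.timestamps) != len(self.frames):
            raise ValueError("timestamps and frames differ in length")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        h, w = self.frames[0].shape[:2]
        for i, f in enumerate(self.frames):
            if f.shape[:2] != (h, w):
                raise ValueError(
                    f"dimension mismatch: frame {i} is {f.shape[:2]}, expected {(h, w)}"
                )

    @property
    def height(self) -> int:
        return self.frames[0].shape[0]

    @property
    def width(self) -> int:
        return self.frames[0].shape[1]

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.frames)

    def index_frame(self) -> pd.DataFrame:
        """Frame index and timestamp as a two-column table (CSV-exportable)."""
        return pd.DataFrame(
            {"frame": np.arange(len(self.frames)), "timestamp": self.timestamps}
        )


@dataclasses.dataclass(frozen=True)
class ExclusionMask:
    """Union of axis-aligned rectangles to blank out (e.g. timestamp overlays).

    Rectangles are ``(x0, y0, x1, y1)`` in 0-based pixel coordinates with x
    rightward and y downward; intervals are half-open, so a rectangle covers
    ``x0 <= x < x1`` and ``y0 <= y < y1``.
    """

    rectangles: tuple[tuple[int, int, int, int], ...] = ()

    def __init__(self, rectangles: Iterable[Sequence[int]] = ()) -> None:
        rects = tuple(tuple(int(v) for v in r) for r in rectangles)
        for r in rects:
            if len(r) != 4:
                raise ValueError(f"rectangle must have 4 coordinates, got {r}")
            x0, y0, x1, y1 = r
            if x1 < x0 or y1 < y0:
                raise ValueError(f"degenerate rectangle {r}")
        object.__setattr__(self, "rectangles", rects)

    def validate(self, height: int, width: int) -> None:
        for x0, y0, x1, y1 in self.rectangles:
            if x0 < 0 or y0 < 0 or x1 > width or y1 > height:
                raise ValueError(
                    f"rectangle ({x0},{y0},{x1},{y1}) outside {width}x{height} frame"
                )

    def to_array(self, height: int, width: int) -> np.ndarray:
        """Boolean ``H×W`` array, True where pixels are excluded."""
        self.validate(height, width)
        out = np.zeros((height, width), dtype=bool)
        for x0, y0, x1, y1 in self.rectangles:
            out[y0:y1, x0:x1] = True
        return out

    def pixel_count(self, height: int, width: int) -> int:
        """Number of excluded pixels (overlaps counted once)."""
        return int(self.to_array(height, width).sum())


def _sorted_frame_paths(path: Path) -> list[Path]:
    paths = sorted(
        p for p in path.iterdir() if p.suffix.lower() in _FRAME_EXTENSIONS
    )
    if not paths:
        raise ValueError(f"no frames in {path}")
    return paths


def iter_frames(path: str | Path) -> Iterator[np.ndarray]:
    """Stream frames from a directory in filename order, one array at a time.

    This is the constant-memory entry point used by the analysis pipeline;
    :func:`read_sequence` materialises the same frames in memory.
    """
    for p in _sorted_frame_paths(Path(path)):
        yield np.asarray(iio.imread(p))


def read_sequence(path: str | Path, fps: float = 14.0) -> FrameSequence:
    """Read a directory of numbered image frames into a :class:`FrameSequence`.

    Timestamps are synthesised as ``i / fps`` since the lossless frame formats
    carry none.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    frames = [np.asarray(iio.imread(p)) for p in _sorted_frame_paths(Path(path))]
    ts = np.arange(len(frames)) / fps
    return FrameSequence(frames=frames, timestamps=ts, fps=fps)


def write_sequence(path: str | Path, seq: FrameSequence, fmt: str = "pgm") -> list[Path]:
    """Write frames as zero-padded numbered images; returns the paths written.

    PGM (grayscale) and PNG are supported; both are lossless, so a write/read
    round trip is bit-exact.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if fmt not in ("pgm", "png"):
        raise ValueError(f"unsupported format {fmt!r}")
    digits = max(6, len(str(len(seq.frames))))
    written = []
    for i, frame in enumerate(seq.frames):
        if fmt == "pgm" and frame.ndim == 3:
            raise ValueError("PGM cannot store colour frames; use png")
        p = path / f"frame_{i:0{digits}d}.{fmt}"
        iio.imwrite(p, frame)
        written.append(p)
    return written


def to_grayscale(
    frame: np.ndarray, coeffs: tuple[float, float, float] = BT601_COEFFS
) -> np.ndarray:
    """Convert an 8-bit frame to grayscale in [0, 255].

    Colour frames are reduced with the BT.601 integer luma
    ``Y = 0.299 R + 0.587 G + 0.114 B`` (rounded to nearest); already
    grayscale frames pass through unchanged, which makes the operation
    idempotent.  Night-time IR footage arrives grayscale and therefore takes
    the pass-through path, so day and night frames feed the same analysis.
    """
    frame = np.asarray(frame)
    if frame.ndim == 2:
        return frame
    if frame.ndim == 3 and frame.shape[2] == 3:
        y = frame.astype(np.float64) @ np.asarray(coeffs, dtype=np.float64)
        return np.clip(np.rint(y), 0, 255).astype(np.uint8)
    raise ValueError(f"expected HxW or HxWx3 frame, got shape {frame.shape}")


def apply_exclusion(
    frame: np.ndarray, mask: ExclusionMask
) -> tuple[np.ndarray, int]:
    """Zero the excluded rectangles of a frame.

    Returns the masked copy and the number of excluded pixels, which the
    activity index uses to correct its denominator.  Because the excluded
    pixels become constant across all frames, the background model can never
    flag them after warm-up — the particular constant (0) is immaterial.
    """
    h, w = frame.shape[:2]
    excluded = mask.to_array(h, w)
    out = frame.copy()
    out[excluded] = 0
    return out, int(excluded.sum())
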