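"""Binary mask clean-up: one erosion pass with a 5x5 elliptical element.

The raw change mask contains single-pixel speckle from sensor noise and
compression artefacts; a single binary erosion with the rasterised 5x5
ellipse removes isolated responses while only trimming the rim of genuine
motion blobs.  No opening, closing or dilation is applied.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["ELLIPSE_5", "erode", "structuring_element"]

#: 5x5 rasterised ellipse (semi-axes 2.5), anchor at (2, 2) — 13 active cells.
ELLIPSE_5 = np.array(
    [
        [0, 0, 1, 0, 0],
        [1, 1, 1, 1, 1],
        [1, 1, 1, 1, 1],
        [1, 1, 1, 1, 1],
        [0, 0, 1, 0, 0],
    ],
    dtype=np.uint8,
)


def structuring_element(kernel: str | np.ndarray = "ellipse5") -> np.ndarray:
    """Resolve a kernel spec ("ellipse5" or an explicit 0/1 matrix)."""
    if isinstance(kernel, str):
        if kernel == "ellipse5":
            return ELLIPSE_5.copy()
        raise ValueError(f"unknown kernel {kernel!r}")
    se = np.asarray(kernel)
    if not np.isin(se, (0, 1)).all():
        raise ValueError("structuring element must be binary")
    return se.astype(np.uint8)


def erode(mask: np.ndarray, se: np.ndarray | str = "ellipse5") -> np.ndarray:
    """Binary erosion: output pixel is 1 iff every active cell of ``se``
    centred there covers a 1.

    Cells of the element that fall outside the image are treated as
    foreground (non-eroding border), so the frame edge does not erode an
    otherwise solid mask.  Input must be strictly binary (0/1 or bool).

    Returns a uint8 0/1 array of the input shape.
    """
    mask = np.asarray(mask)
    if mask.dtype != bool and not np.isin(mask, (0, 1)).all():
        raise ValueError("erode expects a binary mask")
    se = structuring_element(se)
    out = ndimage.binary_erosion(mask.astype(bool), structure=se.astype(bool),
                                 border_value=1)
    return out.astype(np.uint8)
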