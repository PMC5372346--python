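"""Foreground/background classification of stack voxels.

A voxel is *bright* when its intensity reaches the intensity threshold, and
*foreground* when additionally the ratio of dark to bright voxels among its
26 neighbors stays below the ratio threshold.  The neighborhood test is a
de-noising step: an isolated bright voxel is surrounded by dark neighbors
and is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import Volume

__all__ = ["BinarizeParams", "ForegroundMask", "classify_spots", "foreground_mask"]

# 3x3x3 neighborhood with the center excluded
_NEIGH26 = np.ones((3, 3, 3), dtype=np.int64)
_NEIGH26[1, 1, 1] = 0


@dataclass
class BinarizeParams:
    """Thresholds for the two-stage foreground test.

    intensity_threshold : intensity below which a voxel is a dark spot
        (default 30).
    ratio_threshold : maximum allowed dark/bright neighbor ratio for a
        bright voxel to count as foreground (default 0.3).
    """

    intensity_threshold: float = 30.0
    ratio_threshold: float = 0.3

    def __post_init__(self) -> None:
        if not 0 <= self.intensity_threshold <= 255:
            raise ValueError("intensity_threshold must be in [0, 255]")
        if self.ratio_threshold < 0:
            raise ValueError("ratio_threshold must be >= 0")


@dataclass
class ForegroundMask:
    """Boolean foreground grid with the same dims as its source volume."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]

    def count(self) -> int:
        return int(self.mask.sum())

    def coordinates(self) -> np.ndarray:
        """(n, 3) integer coordinates of foreground voxels, lexicographic."""
        return np.argwhere(self.mask)


def classify_spots(vol: Volume, params: BinarizeParams | None = None) -> np.ndarray:
    """Bright-spot flags: intensity >= intensity_threshold.

    The complement is the dark-spot set ("intensity less than a threshold").
    """
    params = params or BinarizeParams()
    return vol.data >= params.intensity_threshold


def foreground_mask(vol: Volume, params: BinarizeParams | None = None) -> ForegroundMask:
    """Two-stage foreground test over the whole volume.

    A voxel is foreground iff it is bright and ``n_dark / n_bright`` over its
    26 neighbors is at most ``ratio_threshold``.  Out-of-bounds neighbors
    count as dark, which conservatively shrinks foreground at the image
    border; a bright voxel with no bright neighbor has ratio +inf and is
    always rejected.
    """
    params = params or BinarizeParams()
    bright = classify_spots(vol, params)
    n_bright = ndimage.convolve(
        bright.astype(np.int64), _NEIGH26, mode="constant", cval=0
    )
    n_dark = 26 - n_bright
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(n_bright > 0, n_dark / np.maximum(n_bright, 1), np.inf)
    return ForegroundMask(bright & (ratio <= params.ratio_threshold))
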