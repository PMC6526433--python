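"""Superpixel size equalization and assembly of the superpixel matrix.

SLIC superpixels have unequal pixel counts, but the eigen-analysis needs
a fixed-length vector per superpixel. Every superpixel is brought to the
mean length M: short ones are padded by repeating their own last
raster-order value (no foreign intensities are introduced), long ones
are truncated to their first M raster-order values. Columns of the
resulting M x N matrix S are ordered by ascending superpixel label, so
column index j always refers to superpixel label j.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .image_io import GrayImage
from .superpixel import SuperpixelPartition


@dataclass(frozen=True)
class SuperpixelMatrix:
    """The M x N equal-length superpixel matrix.

    ``S[:, j]`` is the equalized intensity sequence of superpixel
    ``column_order[j]``; column_order is the identity (ascending label)
    but kept explicit for diagnostics.
    """

    S: np.ndarray = field(repr=False)
    M: int
    N: int
    column_order: np.ndarray

    def __post_init__(self) -> None:
        if self.S.shape != (self.M, self.N):
            raise ValidationError(
                f"matrix shape {self.S.shape} inconsistent with M={self.M}, N={self.N}"
            )


def mean_superpixel_size(partition: SuperpixelPartition) -> int:
    """Mean superpixel pixel count, rounded half away from zero; >= 1."""
    mean = float(np.mean(partition.sizes))
    return max(1, int(math.floor(mean + 0.5)))


def equalize_column(values: np.ndarray, M: int) -> np.ndarray:
    """Bring one intensity sequence to length M (pad-last / truncate-head)."""
    n = len(values)
    if n >= M:
        return np.asarray(values[:M], dtype=np.float64)
    out = np.empty(M, dtype=np.float64)
    out[:n] = values
    out[n:] = values[-1]
    return out


def equalize_superpixels(
    partition: SuperpixelPartition, img: GrayImage
) -> SuperpixelMatrix:
    """Assemble the M x N superpixel matrix from a partition and its image."""
    if partition.shape != img.shape:
        raise ValidationError(
            f"partition shape {partition.shape} does not match image {img.shape}"
        )
    M = mean_superpixel_size(partition)
    N = partition.n_superpixels
    S = np.empty((M, N), dtype=np.float64)
    for j in range(N):
        S[:, j] = equalize_column(partition.intensity_sequence(img, j), M)
    return SuperpixelMatrix(S, M, N, np.arange(N))
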