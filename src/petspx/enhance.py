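"""Piecewise linear contrast enhancement.

High-uptake structures in a PET slice sit in the upper intensity range;
the stretch maps the band above a threshold T linearly onto [B, 255]
while leaving the band below untouched:

    I_enh = I                      if I <  T
    I_enh = s * (I - T) + B        if I >= T

With the defaults T = 110, B = 200, s = 55/145 the top of the range is a
fixed point (255 -> 55/145 * 145 + 200 = 255) and the threshold maps to
the output base (110 -> 200), so everything at or above T is compressed
into the bright band [200, 255], boosting tumor-to-background contrast.

``branch_mode="as_printed"`` swaps the two branches (identity for
I >= T, stretch below); that variant is non-monotone across the
threshold and is kept only for literal reproduction of that reading of
the transfer function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .image_io import GrayImage

DEFAULT_THRESHOLD = 110.0
DEFAULT_OUT_BASE = 200.0
DEFAULT_SLOPE = 55.0 / 145.0


@dataclass(frozen=True)
class EnhancementParams:
    threshold: float = DEFAULT_THRESHOLD
    out_base: float = DEFAULT_OUT_BASE
    slope: float = DEFAULT_SLOPE
    branch_mode: str = "stretch_high"

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 255.0:
            raise ValidationError(f"threshold {self.threshold} outside [0, 255]")
        if self.slope <= 0.0:
            raise ValidationError(f"slope must be positive, got {self.slope}")
        if self.branch_mode not in ("stretch_high", "as_printed"):
            raise ValidationError(
                f"branch_mode must be 'stretch_high' or 'as_printed', "
                f"got {self.branch_mode!r}"
            )


def enhance_image(img: GrayImage, params: EnhancementParams | None = None) -> GrayImage:
    """Apply the piecewise linear stretch per pixel; output clipped to [0, 255]."""
    if params is None:
        params = EnhancementParams()
    I = img.pixels
    stretched = params.slope * (I - params.threshold) + params.out_base
    if params.branch_mode == "stretch_high":
        out = np.where(I >= params.threshold, stretched, I)
    else:  # as_printed: identity on I >= threshold, stretch below
        out = np.where(I >= params.threshold, I, stretched)
    return GrayImage(np.clip(out, 0.0, 255.0))
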