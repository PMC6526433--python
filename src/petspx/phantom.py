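"""Synthetic PET-like phantom slices with pixel-level ground truth.

A phantom emulates the features of a single FDG-PET slice the pipeline
exploits: a low, smoothly varying background (soft tissue), a few
moderate-uptake "organ" blobs (focal physiologic uptake), and one or
more small, intense hot spots (tumors, high tracer uptake), all softened
by a Gaussian point-spread function and degraded by noise. Ground truth
is the union of the *unblurred* tumor disks — evaluation tolerates the
blur-induced boundary softness through the overlap threshold rather
than by eroding the truth.

Noise is additive Gaussian by default; a Poisson option scales the
variance with the local mean, closer to the count statistics of real
PET, and is exercised in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ValidationError
from .image_io import GrayImage

Disk = tuple[tuple[float, float], float, float]  # (center (row, col), radius, level)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity layout of one synthetic slice.

    Levels follow the uptake ordering of a PET hot-spot study:
    tumor level > organ level > background level (validated).
    """

    height: int = 256
    width: int = 256
    background_level: float = 40.0
    organ_blobs: tuple[Disk, ...] = ()
    tumors: tuple[Disk, ...] = ()
    background_ripple: float = 0.0  # amplitude of a smooth background gradient
    psf_sigma: float = 1.5
    noise_sigma: float = 5.0
    noise_model: str = "gaussian"  # or "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 16 or self.width < 16:
            raise ValidationError("phantom must be at least 16x16")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValidationError(f"unknown noise model {self.noise_model!r}")
        max_organ = max((lvl for _, _, lvl in self.organ_blobs), default=None)
        min_tumor = min((lvl for _, _, lvl in self.tumors), default=None)
        if max_organ is not None and max_organ <= self.background_level:
            raise ValidationError("organ level must exceed background level")
        if min_tumor is not None:
            floor = max_organ if max_organ is not None else self.background_level
            if min_tumor <= floor:
                raise ValidationError("tumor level must exceed organ and background")
        for (r, c), rad, _ in self.tumors:
            if r - rad < 0 or r + rad > self.height - 1 or c - rad < 0 or c + rad > self.width - 1:
                raise ValidationError(
                    f"tumor at ({r}, {c}) radius {rad} extends outside the image"
                )


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def generate_phantom(spec: PhantomSpec) -> tuple[GrayImage, np.ndarray]:
    """Render a phantom and its ground-truth tumor mask.

    Painting order is background, organ blobs, tumors (later layers
    overwrite), then PSF blur, then noise, then clipping to [0, 255].
    Deterministic for a fixed spec (the seed lives in the spec).
    """
    shape = (spec.height, spec.width)
    img = np.full(shape, spec.background_level, dtype=np.float64)
    if spec.background_ripple > 0.0:
        rr, cc = np.mgrid[: spec.height, : spec.width]
        img += spec.background_ripple * (
            np.sin(2 * np.pi * rr / spec.height) * np.cos(2 * np.pi * cc / spec.width)
        )
    for center, radius, level in spec.organ_blobs:
        img[_disk_mask(shape, center, radius)] = level
    truth = np.zeros(shape, dtype=bool)
    for center, radius, level in spec.tumors:
        d = _disk_mask(shape, center, radius)
        img[d] = level
        truth |= d
    if spec.psf_sigma > 0.0:
        img = gaussian_filter(img, sigma=spec.psf_sigma)
    rng = np.random.default_rng(spec.seed)
    if spec.noise_model == "gaussian":
        if spec.noise_sigma > 0.0:
            img = img + rng.normal(0.0, spec.noise_sigma, size=shape)
    else:  # poisson: variance proportional to the local mean
        img = rng.poisson(np.clip(img, 0.0, None)).astype(np.float64)
    return GrayImage(np.clip(img, 0.0, 255.0)), truth


def default_phantom_spec(seed: int = 0, n_tumors: int | None = None) -> PhantomSpec:
    """A randomized study-condition phantom: 256x256, background 40 with a
    gentle ripple, 1-2 organ blobs (level 100, radius 10-20), 1-3 tumors
    (level 230, radius 6-14), PSF sigma 1.5, Gaussian noise sigma 5.

    Tumor centers keep a margin from the border and from each other so
    each truth lesion is a distinct component.
    """
    rng = np.random.default_rng(seed)
    h = w = 256
    if n_tumors is None:
        n_tumors = int(rng.integers(1, 4))
    organs: list[Disk] = []
    for _ in range(int(rng.integers(1, 3))):
        rad = float(rng.uniform(10, 20))
        r = float(rng.uniform(rad + 4, h - rad - 5))
        c = float(rng.uniform(rad + 4, w - rad - 5))
        organs.append(((r, c), rad, 100.0))
    tumors: list[Disk] = []
    attempts = 0
    while len(tumors) < n_tumors and attempts < 200:
        attempts += 1
        rad = float(rng.uniform(6, 14))
        r = float(rng.uniform(rad + 8, h - rad - 9))
        c = float(rng.uniform(rad + 8, w - rad - 9))
        if any(
            np.hypot(r - r0, c - c0) < rad + rad0 + 8 for (r0, c0), rad0, _ in tumors
        ):
            continue
        tumors.append(((r, c), rad, 230.0))
    return PhantomSpec(
        height=h,
        width=w,
        background_level=40.0,
        organ_blobs=tuple(organs),
        tumors=tuple(tumors),
        background_ripple=8.0,
        psf_sigma=1.5,
        noise_sigma=5.0,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
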