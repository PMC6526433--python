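"""Image reading/writing and the canonical intensity convention.

All pipeline stages operate on :class:`GrayImage`: a 2-D raster of real
numbers in [0, 255]. Values are kept as floats end to end — the contrast
stretch produces non-integer outputs (slope 55/145) and re-quantizing
between stages would accumulate rounding error. Quantization happens only
when a file is written (round half to even, then cast to uint8).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import numpy as np
from PIL import Image

from .errors import ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .delineate import SegmentationResult

#: Minimum image side length accepted by the pipeline.
MIN_SIDE = 16

#: Rec. 601 luma weights for collapsing RGB to grayscale.
_REC601 = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grayscale raster with intensities in [0, 255].

    Parameters
    ----------
    pixels
        2-D float array; every value finite and inside [0, 255].
    """

    pixels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValidationError(f"expected a 2-D raster, got ndim={px.ndim}")
        if px.shape[0] < MIN_SIDE or px.shape[1] < MIN_SIDE:
            raise ValidationError(
                f"image {px.shape[0]}x{px.shape[1]} smaller than the "
                f"{MIN_SIDE}x{MIN_SIDE} pipeline minimum"
            )
        if not np.all(np.isfinite(px)):
            raise ValidationError("image contains non-finite intensities")
        if px.min() < 0.0 or px.max() > 255.0:
            raise ValidationError(
                f"intensities outside [0, 255]: min={px.min()}, max={px.max()}"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    @classmethod
    def from_array(cls, arr: np.ndarray, rescale: bool = False) -> "GrayImage":
        """Build a GrayImage from an arbitrary 2-D intensity array.

        With ``rescale`` the values are mapped linearly so min -> 0 and
        max -> 255 (a constant array maps to all zeros); otherwise values
        are clipped into [0, 255].
        """
        arr = np.asarray(arr, dtype=np.float64)
        if arr.ndim != 2:
            raise ValidationError(f"expected a 2-D array, got ndim={arr.ndim}")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("array contains non-finite values")
        if rescale:
            lo, hi = float(arr.min()), float(arr.max())
            if hi > lo:
                arr = (arr - lo) / (hi - lo) * 255.0
            else:
                arr = np.zeros_like(arr)
        else:
            arr = np.clip(arr, 0.0, 255.0)
        return cls(arr)


def load_image(path: str | Path, rescale: bool = False) -> GrayImage:
    """Read a raster image (PNG/TIFF/BMP) as a :class:`GrayImage`.

    Multichannel inputs are collapsed to luminance with Rec. 601 weights.
    ``rescale`` maps the observed range linearly onto [0, 255]; without it
    values are clipped (so already-8-bit inputs pass through unchanged).
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im, dtype=np.float64)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image file {path}: {exc}") from exc
    if arr.ndim == 3:
        arr = arr[..., :3] @ _REC601
    return GrayImage.from_array(arr, rescale=rescale)


def quantize_u8(pixels: np.ndarray) -> np.ndarray:
    """[0,255] floats -> uint8, round half to even (numpy's rint)."""
    return np.rint(np.clip(pixels, 0.0, 255.0)).astype(np.uint8)


def save_gray_png(img: GrayImage | np.ndarray, path: str | Path) -> Path:
    """Write a grayscale raster to an 8-bit PNG."""
    px = img.pixels if isinstance(img, GrayImage) else np.asarray(img)
    path = Path(path)
    Image.fromarray(quantize_u8(px), mode="L").save(path)
    return path


def save_labels_png(labels: np.ndarray, path: str | Path) -> Path:
    """Export a superpixel label map as a 16-bit PNG for inspection."""
    path = Path(path)
    Image.fromarray(labels.astype(np.uint16), mode="I;16").save(path)
    return path


def _overlay_rgb(result: "SegmentationResult") -> np.ndarray:
    """Input image as RGB with the mask boundary painted red."""
    if result.image is None:
        base = np.zeros(result.mask.shape, dtype=np.uint8)
    else:
        base = quantize_u8(result.image.pixels)
    rgb = np.stack([base] * 3, axis=-1)
    from scipy.ndimage import binary_erosion

    boundary = result.mask & ~binary_erosion(result.mask)
    rgb[boundary] = (255, 0, 0)
    return rgb


def _heatmap_rgb(heatmap: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Render the distance raster with a perceptually uniform colormap."""
    import matplotlib

    lo, hi = float(heatmap.min()), float(heatmap.max())
    norm = (heatmap - lo) / (hi - lo) if hi > lo else np.zeros_like(heatmap)
    cmap = matplotlib.colormaps["viridis"]
    rgba = cmap(norm)
    return (rgba[..., :3] * 255).astype(np.uint8), lo, hi


ALL_FORMATS = frozenset({"mask", "contour_overlay", "heatmap", "report"})


def save_outputs(
    result: "SegmentationResult",
    out_dir: str | Path,
    formats: Iterable[str] = ALL_FORMATS,
) -> list[Path]:
    """Write segmentation artifacts and return the paths, sorted.

    Formats: ``mask`` (8-bit PNG, 0 background / 255 tumor),
    ``contour_overlay`` (RGB PNG, tumor boundary in red on the input),
    ``heatmap`` (RGB PNG with a viridis scale plus a sidecar text file
    recording the scale limits), ``report`` (JSON summary).
    """
    out_dir = Path(out_dir)
    formats = set(formats)
    unknown = formats - ALL_FORMATS
    if unknown:
        raise ValidationError(f"unknown output formats: {sorted(unknown)}")
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".petspx-write-probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc

    paths: list[Path] = []
    if "mask" in formats:
        p = out_dir / "mask.png"
        Image.fromarray(np.where(result.mask, 255, 0).astype(np.uint8), "L").save(p)
        paths.append(p)
    if "contour_overlay" in formats:
        p = out_dir / "contour_overlay.png"
        Image.fromarray(_overlay_rgb(result), "RGB").save(p)
        paths.append(p)
    if "heatmap" in formats:
        rgb, lo, hi = _heatmap_rgb(result.heatmap)
        p = out_dir / "heatmap.png"
        Image.fromarray(rgb, "RGB").save(p)
        sidecar = out_dir / "heatmap_scale.txt"
        sidecar.write_text(f"min {lo!r}\nmax {hi!r}\ncolormap viridis\n")
        paths.extend([p, sidecar])
    if "report" in formats:
        p = out_dir / "report.json"
        p.write_text(json.dumps(result.report, indent=2, sort_keys=True) + "\n")
        paths.append(p)
    return sorted(paths)


def save_scatter_plot(coords: np.ndarray, path: str | Path) -> Path:
    """Plot principal-component coordinates of the superpixels.

    ``coords`` is an (N+1) x K array whose last row is the average
    superpixel (the origin); it is drawn as a red asterisk, the rest as
    dots. Only the first two components are plotted.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = np.asarray(coords, dtype=float)
    xs = coords[:, 0]
    ys = coords[:, 1] if coords.shape[1] > 1 else np.zeros_like(xs)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(xs[:-1], ys[:-1], ".", color="tab:blue", label="superpixels")
    ax.plot(xs[-1], ys[-1], "r*", markersize=12, label="average superpixel")
    ax.set_xlabel("principal component 1")
    ax.set_ylabel("principal component 2")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
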