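"""SLIC over-segmentation of the enhanced image.

The pipeline treats the partition as opaque beyond these invariants:
every pixel carries exactly one label, labels run 0..N-1 with no empty
label, each superpixel is 4-connected, and sizes sum to the pixel count.
SLIC itself (localized k-means in joint intensity-position space with a
compactness weight) is delegated to scikit-image; a post-pass guarantees
the invariants regardless of the backend's connectivity handling by
merging orphan components into the largest adjacent superpixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation
from skimage.measure import label as _cc_label
from skimage.segmentation import slic as _skimage_slic

from .errors import ValidationError
from .image_io import GrayImage

#: Defaults chosen to land in the few-hundred-superpixel regime on
#: images a few hundred pixels on a side.
DEFAULT_TARGET_N = 700
DEFAULT_COMPACTNESS = 10.0
DEFAULT_ITERATIONS = 10

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class SuperpixelPartition:
    """A total partition of the image into N connected superpixels.

    ``pixel_lists[j]`` holds superpixel j's pixel coordinates as an
    (n_j, 2) array of (row, col) in raster-scan order; this ordering is
    load-bearing downstream (it defines which value pads and which
    values survive truncation during size equalization).
    """

    labels: np.ndarray = field(repr=False)
    n_superpixels: int
    sizes: np.ndarray
    pixel_lists: list[np.ndarray] = field(repr=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def intensity_sequence(self, img: GrayImage, label: int) -> np.ndarray:
        """Raster-order intensities of one superpixel."""
        coords = self.pixel_lists[label]
        return img.pixels[coords[:, 0], coords[:, 1]]


def _partition_from_labels(labels: np.ndarray) -> SuperpixelPartition:
    """Relabel consecutively and build sizes / raster-order pixel lists."""
    uniq, inv = np.unique(labels, return_inverse=True)
    labels = inv.reshape(labels.shape)
    n = len(uniq)
    flat = labels.ravel()
    sizes = np.bincount(flat, minlength=n)
    order = np.argsort(flat, kind="stable")  # grouped by label, raster order within
    rows, cols = np.unravel_index(order, labels.shape)
    coords = np.column_stack([rows, cols])
    bounds = np.cumsum(sizes)[:-1]
    pixel_lists = np.split(coords, bounds)
    return SuperpixelPartition(labels, n, sizes, pixel_lists)


def _merge_orphans(labels: np.ndarray, max_rounds: int = 16) -> np.ndarray:
    """Force every label to be a single 4-connected component.

    Any secondary component of a label is reassigned to the largest
    4-adjacent superpixel; ties break toward the smallest label.
    """
    labels = labels.copy()
    for _ in range(max_rounds):
        cc = _cc_label(labels, connectivity=1, background=-1)
        ncc = cc.max()
        if ncc == len(np.unique(labels)):
            break
        cc_flat, lab_flat = cc.ravel(), labels.ravel()
        cc_sizes = np.bincount(cc_flat)
        cc_owner = np.zeros(ncc + 1, dtype=labels.dtype)
        cc_owner[cc_flat] = lab_flat
        sp_sizes = np.bincount(lab_flat)
        # keep, per label, only its largest component
        keep = {}
        for comp in range(1, ncc + 1):
            owner = cc_owner[comp]
            if owner not in keep or cc_sizes[comp] > cc_sizes[keep[owner]]:
                keep[owner] = comp
        for comp in range(1, ncc + 1):
            if keep[cc_owner[comp]] == comp:
                continue
            mask = cc == comp
            ring = binary_dilation(mask, structure=_CROSS) & ~mask
            neighbors = np.unique(labels[ring])
            neighbors = neighbors[neighbors != cc_owner[comp]]
            if len(neighbors) == 0:
                continue
            target = neighbors[np.argmax(sp_sizes[neighbors])]
            labels[mask] = target
    return labels


def extract_superpixels(
    img: GrayImage,
    target_n: int = DEFAULT_TARGET_N,
    compactness: float = DEFAULT_COMPACTNESS,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int = 0,
) -> SuperpixelPartition:
    """Partition the image into roughly ``target_n`` superpixels.

    The resulting count N may differ from ``target_n`` (grid placement
    and connectivity enforcement both perturb it) and is reported on the
    returned partition. ``seed`` is accepted for interface stability;
    the SLIC backend is deterministic.

    Parameters
    ----------
    target_n
        Requested superpixel count; must satisfy 2 <= target_n <= pixels/4.
    compactness
        Spatial-regularity weight on the 0-255 intensity scale; larger
        values give squarer superpixels.
    iterations
        Number of SLIC update iterations.
    """
    del seed  # deterministic backend
    total = img.height * img.width
    if not 2 <= target_n <= total // 4:
        raise ValidationError(
            f"target_n={target_n} outside the valid range [2, {total // 4}] "
            f"for a {img.height}x{img.width} image"
        )
    # the backend rescales intensities to [0, 1] by the image's own range
    # before weighing them against spatial distance; divide compactness by
    # that range so the parameter stays defined on the 0-255 intensity scale
    intensity_range = float(np.ptp(img.pixels))
    backend_compactness = (
        compactness / intensity_range if intensity_range > 0 else compactness
    )
    labels = _skimage_slic(
        img.pixels,
        n_segments=target_n,
        compactness=backend_compactness,
        max_num_iter=iterations,
        channel_axis=None,
        convert2lab=False,
        enforce_connectivity=True,
        start_label=0,
    )
    labels = _merge_orphans(labels)
    return _partition_from_labels(labels)
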