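import numpy as np
import pytest

from petspx import (
    GrayImage,
    PhantomSpec,
    extract_superpixels,
    generate_phantom,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def small_phantom():
    """A clean 96x96 slice with one hot disk — fast, deterministic input."""
    spec = PhantomSpec(
        height=96,
        width=96,
        background_level=40.0,
        organ_blobs=(),
        tumors=(((48.0, 48.0), 9.0, 230.0),),
        psf_sigma=1.0,
        noise_sigma=3.0,
        seed=7,
    )
    return generate_phantom(spec)


@pytest.fixture
def small_partition(small_phantom):
    img, _ = small_phantom
    return extract_superpixels(img, target_n=100)


@pytest.fixture
def constant_image():
    return GrayImage(np.full((32, 32), 50.0))


def assert_valid_partition(partition):
    """The partition invariants every superpixel extraction must satisfy."""
    from skimage.measure import label as cc_label

    labels = partition.labels
    n = partition.n_superpixels
    assert labels.min() == 0 and labels.max() == n - 1
    counts = np.bincount(labels.ravel(), minlength=n)
    assert (counts > 0).all(), "every label must be non-empty"
    assert counts.sum() == labels.size
    assert np.array_equal(counts, partition.sizes)
    # each superpixel is a single 4-connected component
    assert cc_label(labels, connectivity=1, background=-1).max() == n
    # pixel lists: raster-scan order, consistent with the label map
    for j in (0, n // 2, n - 1):
        coords = partition.pixel_lists[j]
        assert len(coords) == partition.sizes[j]
        flat = coords[:, 0] * labels.shape[1] + coords[:, 1]
        assert (np.diff(flat) > 0).all(), "pixel list must be raster-ordered"
        assert (labels[coords[:, 0], coords[:, 1]] == j).all()
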