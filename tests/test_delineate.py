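import numpy as np
import pytest

from petspx import (
    ValidationError,
    build_heatmap,
    extract_contours,
    labels_to_mask,
    morph_clean,
)
from petspx.superpixel import _partition_from_labels


@pytest.fixture
def quad_partition():
    labels = np.zeros((16, 16), dtype=np.int64)
    labels[:8, 8:] = 1
    labels[8:, :8] = 2
    labels[8:, 8:] = 3
    return _partition_from_labels(labels)


class TestLabelsToMask:
    def test_empty_set_gives_empty_mask(self, quad_partition):
        assert not labels_to_mask(set(), quad_partition).any()

    def test_all_labels_give_full_mask(self, quad_partition):
        assert labels_to_mask({0, 1, 2, 3}, quad_partition).all()

    def test_pixel_count_conserved(self, quad_partition):
        mask = labels_to_mask({2}, quad_partition)
        assert mask.sum() == quad_partition.sizes[2]
        assert (quad_partition.labels[mask] == 2).all()

    def test_invalid_label_rejected(self, quad_partition):
        with pytest.raises(ValidationError):
            labels_to_mask({9}, quad_partition)


class TestMorphClean:
    def test_radius_zero_is_identity(self, rng):
        mask = rng.random((30, 30)) > 0.5
        assert np.array_equal(morph_clean(mask, 0), mask)

    def test_isolated_pixel_removed(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[10, 10] = True
        assert not morph_clean(mask, 1).any()

    def test_large_square_preserved_up_to_corner_rounding(self):
        # a diamond-shaped radius-1 disk cannot reproduce sharp corners,
        # so opening clips at most the 4 corner pixels of a big square
        mask = np.zeros((40, 40), dtype=bool)
        mask[10:30, 10:30] = True
        opened = morph_clean(mask, 1)
        lost = mask & ~opened
        assert lost.sum() <= 4
        assert {tuple(p) for p in np.argwhere(lost)} <= {
            (10, 10), (10, 29), (29, 10), (29, 29)
        }
        assert opened[11:29, 11:29].all()

    def test_anti_extensive_and_idempotent(self, rng):
        mask = rng.random((40, 40)) > 0.4
        opened = morph_clean(mask, 2)
        assert not (opened & ~mask).any()  # output subset of input
        assert opened.sum() <= mask.sum()
        assert np.array_equal(morph_clean(opened, 2), opened)

    def test_negative_radius_rejected(self):
        with pytest.raises(ValidationError):
            morph_clean(np.zeros((5, 5), bool), -1)


class TestExtractContours:
    def test_empty_mask(self):
        assert extract_contours(np.zeros((10, 10), bool)) == []

    @pytest.mark.parametrize("r,c", [(1, 1), (3, 7), (5, 5)])
    def test_rectangle_perimeter_in_edge_steps(self, r, c):
        mask = np.zeros((12, 12), dtype=bool)
        mask[2 : 2 + r, 3 : 3 + c] = True
        contours = extract_contours(mask)
        assert len(contours) == 1
        loop = contours[0]
        assert np.array_equal(loop[0], loop[-1])  # closed
        assert len(loop) - 1 == 2 * (r + c)
        # unit steps along pixel edges
        steps = np.abs(np.diff(loop, axis=0)).sum(axis=1)
        assert (steps == 1).all()

    def test_two_blobs_ordered_by_top_left(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[12:15, 2:5] = True  # lower-left blob
        mask[2:5, 10:13] = True  # upper-right blob
        contours = extract_contours(mask)
        assert len(contours) == 2
        assert contours[0][:, 0].min() < contours[1][:, 0].min()

    def test_diagonal_pixels_form_one_contour(self):
        # 8-connected component joined only at a corner
        mask = np.zeros((10, 10), dtype=bool)
        mask[3, 3] = mask[4, 4] = True
        contours = extract_contours(mask)
        assert len(contours) == 1
        assert len(contours[0]) - 1 == 8  # both pixel boundaries traversed

    def test_hole_boundary_not_returned(self):
        mask = np.zeros((12, 12), dtype=bool)
        mask[2:9, 2:9] = True
        mask[4:7, 4:7] = False
        contours = extract_contours(mask)
        assert len(contours) == 1  # outer boundary only

    def test_every_contour_encloses_mask_pixels(self, rng):
        mask = rng.random((25, 25)) > 0.7
        for loop in extract_contours(mask):
            r0 = int(loop[:, 0].min())
            # the row just below the topmost boundary edge contains mask pixels
            cols = loop[loop[:, 0] == r0][:, 1].astype(int)
            assert mask[r0, cols.min() : cols.max()].any()


class TestBuildHeatmap:
    def test_zero_distances_give_zero_raster(self, quad_partition):
        heat, lo, hi = build_heatmap(np.zeros(4), quad_partition)
        assert (heat == 0).all() and lo == hi == 0.0

    def test_support_matches_nonzero_superpixel(self, quad_partition):
        heat, lo, hi = build_heatmap(np.array([0.0, 0.0, 5.0, 0.0]), quad_partition)
        assert (heat[quad_partition.labels == 2] == 5.0).all()
        assert (heat[quad_partition.labels != 2] == 0.0).all()
        assert (lo, hi) == (0.0, 5.0)

    def test_constant_within_each_superpixel(self, small_partition, rng):
        D = rng.uniform(0, 10, size=small_partition.n_superpixels)
        heat, _, _ = build_heatmap(D, small_partition)
        for j in (0, small_partition.n_superpixels - 1):
            vals = heat[small_partition.labels == j]
            assert (vals == vals[0]).all()
        assert set(np.unique(heat)) <= set(D)

    def test_length_mismatch_rejected(self, quad_partition):
        with pytest.raises(ValidationError):
            build_heatmap(np.zeros(3), quad_partition)
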