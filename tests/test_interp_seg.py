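import numpy as np
import pytest

from esovol import (
    CTVolume,
    HUWindow,
    KeySliceSet,
    SegmentationMask,
    SliceContour,
    apply_hu_window,
    edit_mask,
    interpolate_contours,
    rasterize,
    segment_manual,
    volume_from_mask,
)
from esovol.errors import DegenerateInputError, GeometryError, ValidationError
from .conftest import centered_grid, circle_contour


class TestInterpolateContours:
    def test_identical_key_circles_propagate_unchanged(self, square_grid):
        c0, c8 = circle_contour(0, 12.0), circle_contour(8, 12.0)
        mask = interpolate_contours(KeySliceSet([c0, c8]), square_grid)
        ref = rasterize(c0, square_grid)
        for k in range(9):
            np.testing.assert_array_equal(mask.mask[k], ref)
        assert not mask.mask[9:].any()

    def test_concentric_circles_interpolate_radius_linearly(self, square_grid):
        keys = KeySliceSet([circle_contour(0, 10.0), circle_contour(10, 20.0)])
        mask = interpolate_contours(keys, square_grid)
        area = mask.mask[5].sum() * square_grid.pixel_area_mm2
        r_mid = np.sqrt(area / np.pi)
        assert r_mid == pytest.approx(15.0, abs=square_grid.dx)  # one pixel

    def test_adjacent_keys_create_no_intermediates(self, square_grid):
        keys = KeySliceSet([circle_contour(3, 10.0), circle_contour(4, 15.0)])
        mask = interpolate_contours(keys, square_grid)
        assert mask.mask[3].any() and mask.mask[4].any()
        assert not np.delete(mask.mask, [3, 4], axis=0).any()

    def test_key_slices_reproduced_bit_exactly(self, square_grid):
        rng = np.random.default_rng(4)
        th = np.sort(rng.uniform(0, 2 * np.pi, 24))
        r = 10 + rng.uniform(-2, 2, 24)
        blob = SliceContour(2, np.column_stack([r * np.cos(th), r * np.sin(th)]))
        keys = KeySliceSet([blob, circle_contour(9, 14.0)])
        mask = interpolate_contours(keys, square_grid)
        np.testing.assert_array_equal(mask.mask[2], rasterize(blob, square_grid))
        np.testing.assert_array_equal(mask.mask[9], rasterize(keys.contours[1], square_grid))

    def test_z_reflection_symmetry(self, square_grid):
        keys = KeySliceSet([circle_contour(0, 10.0), circle_contour(10, 20.0)])
        fwd = interpolate_contours(keys, square_grid)
        n = square_grid.n_slices
        flipped = KeySliceSet([circle_contour(n - 11, 20.0), circle_contour(n - 1, 10.0)])
        rev = interpolate_contours(flipped, square_grid)
        np.testing.assert_array_equal(rev.mask[::-1], fwd.mask)

    def test_adjacent_slice_change_bounded_on_convex_phantom(self, square_grid):
        keys = KeySliceSet([circle_contour(0, 8.0), circle_contour(10, 20.0)])
        mask = interpolate_contours(keys, square_grid)
        sym_key = np.logical_xor(mask.mask[0], mask.mask[10]).sum()
        for k in range(10):
            step = np.logical_xor(mask.mask[k], mask.mask[k + 1]).sum()
            assert step <= sym_key

    def test_key_slice_outside_grid(self, square_grid):
        keys = KeySliceSet([circle_contour(0, 10.0), circle_contour(99, 10.0)])
        with pytest.raises(GeometryError):
            interpolate_contours(keys, square_grid)

    def test_empty_rasterization_is_degenerate(self):
        grid = centered_grid(6, 16, 16, 2.0, 2.0, 2.5)
        tiny = SliceContour(0, np.array([[0.3, 0.3], [0.6, 0.3], [0.45, 0.6]]))
        keys = KeySliceSet([tiny, circle_contour(5, 10.0)])
        with pytest.raises(DegenerateInputError):
            interpolate_contours(keys, grid)


class TestHUWindow:
    def _mask_and_vol(self):
        vox = np.full((3, 8, 8), 40.0, dtype=np.float32)
        vox[1, 2:6, 2:6] = -1000.0  # air lumen
        vol = CTVolume(vox, (1, 1, 2.5))
        mask = SegmentationMask(np.ones_like(vox, dtype=bool), provenance="semiauto")
        return mask, vol

    def test_air_removed_tissue_kept(self):
        mask, vol = self._mask_and_vol()
        out = apply_hu_window(mask, vol, HUWindow(0, 1000))
        assert not out.mask[1, 2:6, 2:6].any()
        assert out.mask.sum() == mask.mask.sum() - 16

    def test_uniform_tissue_unchanged(self):
        vox = np.full((2, 4, 4), 40.0)
        vol = CTVolume(vox, (1, 1, 1))
        mask = SegmentationMask(np.ones_like(vox, dtype=bool), provenance="semiauto")
        out = apply_hu_window(mask, vol)
        np.testing.assert_array_equal(out.mask, mask.mask)

    def test_idempotent_and_monotone(self):
        mask, vol = self._mask_and_vol()
        once = apply_hu_window(mask, vol)
        twice = apply_hu_window(once, vol)
        np.testing.assert_array_equal(once.mask, twice.mask)
        assert not (once.mask & ~mask.mask).any()  # never adds voxels

    def test_inclusive_bounds(self):
        vox = np.array([[[0.0, 1000.0, -0.5, 1000.5]]])
        vol = CTVolume(vox, (1, 1, 1))
        mask = SegmentationMask(np.ones_like(vox, dtype=bool), provenance="semiauto")
        out = apply_hu_window(mask, vol, HUWindow(0, 1000))
        np.testing.assert_array_equal(out.mask[0, 0], [True, True, False, False])

    def test_shape_mismatch(self):
        mask, _ = self._mask_and_vol()
        with pytest.raises(GeometryError):
            apply_hu_window(mask, CTVolume(np.zeros((4, 4, 4)), (1, 1, 1)))

    def test_invalid_window(self):
        with pytest.raises(ValidationError):
            HUWindow(10, 10)

    def test_phantom_lumen_fraction_recovered(self):
        from esovol import PhantomSpec, generate_phantom, truth_contours

        spec = PhantomSpec(shape=(20, 64, 64), spacing=(0.5, 0.5, 1.0), z_first=2, z_last=17,
                           r_outer=12.0, r_lumen=4.0, seed=3)
        vol, _, _ = generate_phantom(spec)
        full = segment_manual(truth_contours(spec, vol), vol)  # outer boundary incl. lumen
        windowed = apply_hu_window(SegmentationMask(full.mask, "semiauto"), vol)
        f = (4.0 / 12.0) ** 2  # lumen area fraction
        assert windowed.voxel_count / full.voxel_count == pytest.approx(1 - f, abs=0.01)


class TestEditMask:
    def _setup(self):
        grid = centered_grid(5, 32, 32, 1.0, 1.0, 2.5)
        mask = SegmentationMask(np.zeros(grid.voxels.shape, dtype=bool), provenance="semiauto")
        return grid, mask

    def test_add_then_remove_is_identity_on_empty(self):
        grid, mask = self._setup()
        region = circle_contour(2, 6.0)
        added = edit_mask(mask, 2, region, "add", grid)
        removed = edit_mask(added, 2, region, "remove", grid)
        assert not removed.mask.any()
        assert len(removed.edits) == 2  # provenance keeps both edits

    def test_remove_whole_slice(self, square_grid):
        c = circle_contour(1, 10.0)
        mask = segment_manual([circle_contour(1, 8.0)], square_grid)
        out = edit_mask(SegmentationMask(mask.mask, "semiauto"), 1, c, "remove", square_grid)
        assert not out.mask[1].any()

    def test_disjoint_add_increases_count_exactly(self):
        grid, mask = self._setup()
        # edges on integer coordinates: centers of the 32-px centered grid
        # sit at half-integers, so a 5x5 mm square covers exactly 25 centers
        sq = SliceContour(3, np.array([[-11.0, -11.0], [-6.0, -11.0], [-6.0, -6.0], [-11.0, -6.0]]))
        out = edit_mask(mask, 3, sq, "add", grid)
        assert out.voxel_count == 25

    def test_slice_out_of_range(self):
        grid, mask = self._setup()
        with pytest.raises(GeometryError):
            edit_mask(mask, 9, circle_contour(9, 5.0), "add", grid)


class TestSegmentManual:
    def test_mask_empty_outside_contoured_range(self, square_grid):
        contours = [circle_contour(k, 10.0) for k in range(3, 8)]
        mask = segment_manual(contours, square_grid)
        assert mask.provenance == "manual"
        assert mask.mask[3:8].all(axis=0).any()
        assert not mask.mask[:3].any() and not mask.mask[8:].any()

    def test_gap_in_slices_lists_missing(self, square_grid):
        contours = [circle_contour(k, 10.0) for k in (2, 3, 6)]
        with pytest.raises(ValidationError, match=r"\[4, 5\]"):
            segment_manual(contours, square_grid)

    def test_equals_interpolation_when_every_slice_is_a_key(self, square_grid):
        radii = np.linspace(8, 18, 9)
        contours = [circle_contour(k, r) for k, r in enumerate(radii)]
        manual = segment_manual(contours, square_grid)
        interp = interpolate_contours(KeySliceSet(contours), square_grid)
        np.testing.assert_array_equal(manual.mask, interp.mask)

    def test_cylinder_volume_matches_analytic(self, square_grid):
        # r=20 mm over all 21 slices of 2.5 mm -> pi r^2 h
        contours = [circle_contour(k, 20.0) for k in range(21)]
        mask = segment_manual(contours, square_grid)
        v = volume_from_mask(mask, square_grid)
        assert v == pytest.approx(np.pi * 400 * 52.5 / 1000, rel=0.01)
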