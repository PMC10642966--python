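import numpy as np
import pytest

from unfoldreg import (DiffeoTransform, UnfoldedMap, make_synthetic_warp,
                       propagate_labels_unfolded, project_to_native,
                       impute_missing, flip_lr, dice_scores,
                       compute_coordinates, project_labels_to_unfolded)
from unfoldreg.evaluation import _subfields_only

TEST_GRID = (64, 32)


def _banded_labels():
    cols = np.zeros(TEST_GRID[1], np.int16)
    bounds = [0, 10, 19, 22, 26, 32]
    for lab, (a, b) in enumerate(zip(bounds[:-1], bounds[1:]), start=1):
        cols[a:b] = lab
    return UnfoldedMap(np.tile(cols, (TEST_GRID[0], 1)))


class TestPropagateUnfolded:
    def test_identity_transforms_copy(self):
        labels = _banded_labels()
        ident = DiffeoTransform.identity(TEST_GRID)
        out = propagate_labels_unfolded(labels, ident, ident)
        assert np.array_equal(out.values, labels.values)

    def test_self_consistency(self):
        """A sample propagated through its own transforms returns its own
        labels exactly."""
        labels = _banded_labels()
        t = make_synthetic_warp(TEST_GRID, 4.0, 10.0, seed=2)
        out = propagate_labels_unfolded(labels, t, t)
        d = dice_scores(labels.values, out.values)
        assert all(v > 0.999 for v in d.values() if np.isfinite(v))

    def test_grid_mismatch(self):
        labels = _banded_labels()
        t = DiffeoTransform.identity((32, 16))
        with pytest.raises(ValueError, match="mismatch"):
            propagate_labels_unfolded(labels, t, t)


class TestProjectToNative:
    def test_self_projection_round_trip(self, default_phantom):
        # full-resolution grid: the round trip is discretization-limited,
        # and coarse grids lose the narrow CA2/CA3 bands
        vol = default_phantom.labels
        coords = compute_coordinates(vol)
        unfolded = project_labels_to_unfolded(vol, coords, shape=(256, 128))
        native, n_missing = project_to_native(coords, unfolded, vol)
        ref = _subfields_only(vol)
        d = dice_scores(ref.voxels, native.voxels)
        assert all(v > 0.95 for v in d.values())
        assert n_missing == 0

    def test_empty_map_gives_background(self, default_phantom):
        coords = compute_coordinates(default_phantom.labels)
        empty = UnfoldedMap(np.zeros(TEST_GRID, np.int16))
        native, _ = project_to_native(coords, empty, default_phantom.labels)
        assert (native.voxels == 0).all()

    def test_half_map_stays_in_half(self, default_phantom):
        coords = compute_coordinates(default_phantom.labels)
        half = np.zeros(TEST_GRID, np.int16)
        half[:, : TEST_GRID[1] // 2] = 1
        native, _ = project_to_native(coords, UnfoldedMap(half),
                                      default_phantom.labels)
        labeled = native.voxels == 1
        assert np.nanmax(coords.pd[labeled]) < 0.55


class TestImpute:
    def test_fills_single_hole(self):
        vals = np.full((8, 8), 2, np.int16)
        vals[4, 4] = 0
        out, n = impute_missing(UnfoldedMap(vals))
        assert out.values[4, 4] == 2 and n == 1

    def test_no_zeros_unchanged(self):
        m = _banded_labels()
        out, n = impute_missing(m)
        assert n == 0 and np.array_equal(out.values, m.values)

    def test_tie_breaks_to_smaller_label(self):
        vals = np.zeros((1, 3), np.int16)
        vals[0, 0] = 1  # Sub
        vals[0, 2] = 2  # CA1, equidistant from the middle pixel
        out, _ = impute_missing(UnfoldedMap(vals))
        assert out.values[0, 1] == 1

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            impute_missing(UnfoldedMap(np.zeros((4, 4), np.int16)))


class TestFlip:
    def test_double_flip_identity(self, default_phantom):
        v = default_phantom.labels
        back = flip_lr(flip_lr(v))
        assert np.array_equal(back.voxels, v.voxels)
        assert np.allclose(back.affine, v.affine)

    def test_centroid_x_negated(self, default_phantom):
        v = default_phantom.labels
        ijk = np.argwhere(v.gray_mask)
        cx = v.world_coords(ijk).mean(axis=0)[0]
        fx = flip_lr(v).world_coords(ijk).mean(axis=0)[0]
        assert abs(fx + cx) < 1e-9

    def test_flip_improves_cross_hemisphere_overlap(self):
        from unfoldreg import (PhantomParams, generate_phantom,
                               moment_rigid_init)
        from unfoldreg.io import LabelVolume
        from unfoldreg.registration import resample_rigid
        left = generate_phantom(PhantomParams(grid_shape=TEST_GRID,
                                              hemisphere="left"), seed=6)
        right = generate_phantom(PhantomParams(grid_shape=TEST_GRID,
                                               hemisphere="right"), seed=6)

        def overlap(moving):
            mask_f = LabelVolume(left.labels.gray_mask.astype(np.int16),
                                 left.labels.affine)
            mask_m = LabelVolume(moving.gray_mask.astype(np.int16),
                                 moving.affine)
            rec = moment_rigid_init(mask_f, mask_m)
            res = resample_rigid(mask_m, mask_f,
                                 rec.parameters["matrix"],
                                 rec.parameters["translation"], order=0)
            a = mask_f.voxels > 0
            b = res > 0
            return 2 * (a & b).sum() / (a.sum() + b.sum())

        assert overlap(flip_lr(right.labels)) > overlap(right.labels)
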