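import numpy as np
import pytest

from unfoldreg import (DiffeoTransform, RegParams, make_synthetic_warp,
                       register_multichannel, build_template,
                       apply_transform, jacobian_determinant,
                       moment_rigid_init, LabelVolume)
from unfoldreg.registration import compose, invert, warp_image

TEST_GRID = (64, 32)


class TestEngine:
    def test_self_registration_is_identity(self, default_stack):
        t = register_multichannel(default_stack, default_stack)
        mag = np.sqrt((t.disp ** 2).sum(axis=0))
        assert np.median(mag) < 0.25

    def test_known_warp_recovery(self, default_stack):
        M = default_stack.as_array()
        t_true = make_synthetic_warp(TEST_GRID, 5.0, 12.0, seed=1)
        F = np.stack([warp_image(M[c], t_true.disp)
                      for c in range(M.shape[0])])
        t_rec = register_multichannel(F, M)
        err = np.sqrt(((t_rec.disp - t_true.disp) ** 2).sum(axis=0))
        assert err.mean() < 1.0
        assert jacobian_determinant(t_rec).min() > 0

    def test_channel_mismatch_rejected(self, default_stack):
        M = default_stack.as_array()
        with pytest.raises(ValueError, match="mismatch"):
            register_multichannel(M, M[:2])

    def test_nan_channel_rejected(self):
        F = np.full((1, 16, 16), np.nan)
        with pytest.raises(ValueError, match="finite"):
            register_multichannel(F, F)


class TestAlgebra:
    def test_compose_with_identity(self):
        t = make_synthetic_warp(TEST_GRID, 5.0, 12.0, seed=1)
        ident = DiffeoTransform.identity(TEST_GRID)
        assert np.abs(compose(ident, t).disp - t.disp).max() < 1e-9

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_inverse_consistency(self, seed):
        t = make_synthetic_warp(TEST_GRID, 5.0, 12.0, seed=seed)
        resid = compose(t, invert(t)).disp
        assert np.sqrt((resid ** 2).sum(axis=0)).max() < 0.1

    def test_double_inversion(self):
        t = make_synthetic_warp(TEST_GRID, 5.0, 12.0, seed=1)
        assert np.abs(invert(invert(t)).disp - t.disp).max() < 0.1

    def test_composition_matches_point_tracing(self):
        a = make_synthetic_warp(TEST_GRID, 5.0, 12.0, seed=1)
        b = make_synthetic_warp(TEST_GRID, 4.0, 10.0, seed=2)
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.uniform(0, TEST_GRID[0] - 1, 100),
                               rng.uniform(0, TEST_GRID[1] - 1, 100)])
        traced = b.map_points(a.map_points(pts))
        composed = compose(a, b).map_points(pts)
        assert np.abs(traced - composed).max() < 0.2

    def test_domain_mismatch(self):
        a = make_synthetic_warp((32, 16), 2.0, 8.0, seed=1)
        b = make_synthetic_warp((64, 32), 2.0, 8.0, seed=1)
        with pytest.raises(ValueError, match="mismatch"):
            compose(a, b)


class TestApplyTransform:
    def test_identity_leaves_image(self):
        rng = np.random.default_rng(0)
        img = rng.random(TEST_GRID)
        ident = DiffeoTransform.identity(TEST_GRID)
        assert np.abs(apply_transform(img, ident) - img).max() < 1e-12

    def test_labels_stay_in_value_set(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 6, TEST_GRID).astype(np.int16)
        t = make_synthetic_warp(TEST_GRID, 4.0, 10.0, seed=3)
        out = apply_transform(labels, t, interp="nearest")
        assert set(np.unique(out)) <= set(np.unique(labels))

    def test_linear_on_labels_rejected(self):
        labels = np.zeros(TEST_GRID, np.int16)
        t = DiffeoTransform.identity(TEST_GRID)
        with pytest.raises(ValueError, match="nearest"):
            apply_transform(labels, t, interp="linear")

    def test_translation_moves_peak(self):
        img = np.zeros(TEST_GRID)
        img[20, 16] = 1.0
        disp = np.zeros((2, *TEST_GRID))
        disp[0] = 3.0  # pull from 3 px further along axis 0
        t = DiffeoTransform(disp)
        out = apply_transform(img, t)
        assert np.unravel_index(out.argmax(), out.shape) == (17, 16)


class TestJacobian:
    def test_identity_is_one(self):
        ident = DiffeoTransform.identity(TEST_GRID)
        assert np.abs(jacobian_determinant(ident) - 1).max() < 1e-12

    def test_uniform_dilation(self):
        ii, jj = np.meshgrid(np.arange(TEST_GRID[0]),
                             np.arange(TEST_GRID[1]), indexing="ij")
        t = DiffeoTransform(np.stack([ii.astype(float), jj.astype(float)]))
        det = jacobian_determinant(t)
        assert abs(det[10, 10] - 4.0) < 1e-9


class TestTemplate:
    def test_identical_stacks_give_identity(self, default_stack):
        res = build_template([default_stack, default_stack,
                              default_stack], n_iter=2)
        for t in res.transforms:
            assert np.median(np.sqrt((t.disp ** 2).sum(axis=0))) < 0.25
        assert np.abs(res.template
                      - np.nan_to_num(default_stack.as_array())).max() < 1e-6

    def test_variance_decreases_on_cohort(self, cohort7):
        from unfoldreg.evaluation import prepare_sample
        preps = [prepare_sample(s.labels, grid_shape=TEST_GRID)
                 for s in cohort7[:4]]
        res = build_template([p.stack for p in preps], n_iter=3)
        assert res.variance[-1] <= res.variance[0]
        assert len(res.history) == 3

    def test_needs_two(self, default_stack):
        with pytest.raises(ValueError):
            build_template([default_stack])


def _ellipsoid(center=(24, 24, 24), radii=(6, 10, 18), shape=(48, 48, 48)):
    zz, yy, xx = np.indices(shape)
    m = (((zz - center[0]) / radii[0]) ** 2
         + ((yy - center[1]) / radii[1]) ** 2
         + ((xx - center[2]) / radii[2]) ** 2) < 1
    return m.astype(np.int16)


class TestMomentInit:
    def test_translation_recovery(self):
        fixed = LabelVolume(_ellipsoid())
        moved = np.roll(_ellipsoid(), (2, -3, 5), axis=(0, 1, 2))
        rec = moment_rigid_init(fixed, LabelVolume(moved))
        assert np.allclose(rec.parameters["translation"], [2, -3, 5],
                           atol=0.5)
        assert np.allclose(rec.parameters["matrix"], np.eye(3), atol=0.05)

    def test_rotation_recovery(self):
        th = np.deg2rad(30)
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        zz, yy, xx = np.indices((48, 48, 48))
        pts = np.stack([zz, yy, xx], -1).reshape(-1, 3) - 24.0
        loc = pts @ R
        rot = (((loc[:, 0]) / 6) ** 2 + ((loc[:, 1]) / 10) ** 2
               + ((loc[:, 2]) / 18) ** 2) < 1
        rec = moment_rigid_init(LabelVolume(_ellipsoid()),
                                LabelVolume(rot.reshape(48, 48, 48)
                                            .astype(np.int16)))
        Rrec = rec.parameters["matrix"]
        angle = np.rad2deg(np.arccos(np.clip((np.trace(Rrec) - 1) / 2,
                                             -1, 1)))
        assert abs(angle - 30) < 2.0

    def test_self_is_identity(self):
        vol = LabelVolume(_ellipsoid())
        rec = moment_rigid_init(vol, vol)
        assert np.abs(rec.parameters["translation"]).max() < 1e-6
        assert np.abs(rec.parameters["matrix"] - np.eye(3)).max() < 1e-6

    def test_empty_mask(self):
        with pytest.raises(ValueError, match="empty"):
            moment_rigid_init(LabelVolume(np.zeros((4, 4, 4), np.int16)),
                              LabelVolume(_ellipsoid()))

    def test_isotropic_falls_back_to_translation(self):
        sphere = _ellipsoid(radii=(10, 10, 10))
        warn = []
        rec = moment_rigid_init(LabelVolume(sphere),
                                LabelVolume(np.roll(sphere, 3, axis=2)),
                                warn=warn)
        assert warn and np.allclose(rec.parameters["matrix"], np.eye(3))
        assert np.allclose(rec.parameters["translation"], [0, 0, 3],
                           atol=0.5)
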