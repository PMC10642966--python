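import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from unfoldreg import (LabelVolume, UnfoldedMap, dice_scores,
                       border_distances, topology_check,
                       paired_one_tailed_t)

label_maps = hnp.arrays(np.int16, (6, 6), elements=st.integers(0, 5))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(a=label_maps, b=label_maps)
def test_dice_symmetric_and_bounded(a, b):
    """Dice is symmetric in its arguments and confined to [0, 1]."""
    d_ab = dice_scores(a, b)
    d_ba = dice_scores(b, a)
    for lab in d_ab:
        x, y = d_ab[lab], d_ba[lab]
        if np.isnan(x):
            assert np.isnan(y)
        else:
            assert x == y and 0.0 <= x <= 1.0


@settings(max_examples=30, deadline=None, derandomize=True)
@given(m=hnp.arrays(np.int16, (8, 8), elements=st.integers(0, 5)))
def test_impute_is_total_and_idempotent(m):
    """Imputation fills every pixel and leaves a filled map unchanged."""
    from unfoldreg import impute_missing
    if not (m > 0).any():
        return
    filled, _ = impute_missing(UnfoldedMap(m))
    assert (filled.values > 0).all()
    again, n = impute_missing(filled)
    assert n == 0 and np.array_equal(again.values, filled.values)


class TestDice:
    def test_identical_maps(self):
        rng = np.random.default_rng(0)
        m = rng.integers(0, 6, (8, 8))
        d = dice_scores(m, m)
        assert all(v == 1.0 for lab, v in d.items() if (m == lab).any())

    def test_hand_counted_example(self):
        ref = np.zeros((10,), int)
        test = np.zeros((10,), int)
        ref[:4] = 1
        test[1:7] = 1  # overlap 3, sizes 4 and 6
        assert dice_scores(ref, test, label_ids=(1,))[1] == pytest.approx(0.6)

    def test_matches_brute_force_on_random_maps(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            a = rng.integers(0, 6, (8, 8))
            b = rng.integers(0, 6, (8, 8))
            d = dice_scores(a, b)
            for lab, got in d.items():
                na = sum(1 for x in a.ravel() if x == lab)
                nb = sum(1 for x in b.ravel() if x == lab)
                ni = sum(1 for x, y in zip(a.ravel(), b.ravel())
                         if x == lab and y == lab)
                if na + nb == 0:
                    assert np.isnan(got)
                else:
                    assert got == 2 * ni / (na + nb)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice_scores(np.zeros((4, 4)), np.zeros((5, 5)))


class TestBorderDistances:
    def test_identical_borders_zero(self):
        vol = np.zeros((6, 6, 6), np.int16)
        vol[:, :, :3] = 1
        vol[:, :, 3:] = 2
        v = LabelVolume(vol)
        res = border_distances(v, v, pairs=((1, 2),))
        assert res["median"] == 0.0

    def test_one_dimensional_offset(self):
        a = np.zeros((1, 1, 21), np.int16)
        a[0, 0, :10] = 1
        a[0, 0, 10:] = 2
        b = np.zeros_like(a)
        b[0, 0, :13] = 1
        b[0, 0, 13:] = 2
        res = border_distances(LabelVolume(a), LabelVolume(b),
                               pairs=((1, 2),))
        assert res["median"] == pytest.approx(3.0)

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(3)
        vol = np.zeros((8, 8, 8), np.int16)
        split = rng.integers(2, 6, size=(8, 8))
        for i in range(8):
            for j in range(8):
                vol[i, j, : split[i, j]] = 1
                vol[i, j, split[i, j]:] = 2
        shift = np.clip(split + rng.integers(-2, 3, size=(8, 8)), 1, 7)
        vol2 = np.zeros_like(vol)
        for i in range(8):
            for j in range(8):
                vol2[i, j, : shift[i, j]] = 1
                vol2[i, j, shift[i, j]:] = 2
        ref = LabelVolume(vol)
        test = LabelVolume(vol2)
        res = border_distances(ref, test, pairs=((1, 2),))

        from unfoldreg.evaluation import _border_mask
        rb = np.argwhere(_border_mask(vol, 1, 2)).astype(float)
        tb = np.argwhere(_border_mask(vol2, 1, 2)).astype(float)
        oracle = np.array([np.min(np.linalg.norm(rb - p, axis=1))
                           for p in tb])
        got = np.sort(res["per_pair"][(1, 2)])
        assert np.abs(np.sort(oracle) - got).max() < 1e-6

    def test_absent_pair_warns(self):
        vol = np.zeros((4, 4, 4), np.int16)
        vol[..., :2] = 1
        vol[..., 2:] = 2
        warn = []
        res = border_distances(LabelVolume(vol), LabelVolume(vol),
                               pairs=((2, 3),), warn=warn)
        assert warn and np.isnan(res["median"])


class TestTopology:
    def test_clean_bands(self):
        cols = np.repeat([1, 2, 3, 4, 5], 4)
        m = np.tile(cols, (10, 1))
        rep = topology_check(m)
        assert rep["n_breaks"] == 0 and rep["n_order_violations"] == 0

    def test_island_is_flagged(self):
        cols = np.repeat([1, 2, 3, 4, 5], 4)
        m = np.tile(cols, (10, 1)).copy()
        m[5, 14] = 2  # CA1 island inside CA3 territory
        rep = topology_check(m)
        assert rep["components"][2] == 2
        assert rep["n_breaks"] >= 1

    def test_skipping_is_allowed_reversal_is_not(self):
        skip = np.tile(np.repeat([1, 2, 4], 4), (5, 1))  # Sub,CA1,CA3
        assert topology_check(skip)["n_order_violations"] == 0
        rev = np.tile(np.repeat([4, 2], 6), (5, 1))  # CA3 then CA1
        assert topology_check(rev)["n_order_violations"] > 0


class TestPairedT:
    def test_closed_form_example(self):
        res = paired_one_tailed_t([1.1, 1.2, 1.3], [1.0, 1.0, 1.0])
        assert res["t"] == pytest.approx(3.4641, abs=1e-3)
        assert res["p"] == pytest.approx(0.0371, abs=5e-4)

    def test_matches_scipy(self):
        from scipy import stats
        rng = np.random.default_rng(0)
        a = rng.random(12)
        b = rng.random(12)
        res = paired_one_tailed_t(a, b)
        ref = stats.ttest_rel(a, b, alternative="greater")
        assert res["t"] == pytest.approx(ref.statistic)
        assert res["p"] == pytest.approx(ref.pvalue)

    def test_equal_vectors(self):
        res = paired_one_tailed_t([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert res["t"] == 0.0 and res["p"] == 0.5

    def test_degenerate_constant_difference(self):
        res = paired_one_tailed_t([1.0, 2.0, 3.0], [0.5, 1.5, 2.5])
        assert res["degenerate"] and res["p"] == 0.0

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            paired_one_tailed_t([1.0, 2.0], [0.0, 1.0])
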