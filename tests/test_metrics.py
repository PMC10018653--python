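"""Closed-form and property tests for the image-quality metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import ndimage, stats

import cbct4d as c
from cbct4d.metrics import (K_MAX, affine_window, cnr, paired_t_test,
                            phase_average, rmse, ssim, tis, tiw)
from cbct4d.volume import Box


def _vol_with(fg_vals, bg_vals):
    """Tiny volume embedding given foreground/background box values."""
    arr = np.zeros((8, 8, 8))
    fg = np.asarray(fg_vals, dtype=float)
    bg = np.asarray(bg_vals, dtype=float)
    arr[0, 0, : fg.size] = fg
    arr[4, 4, : bg.size] = bg
    fg_box = Box((0, 0, 0), (1, 1, fg.size))
    bg_box = Box((4, 4, 0), (5, 5, bg.size))
    return arr, fg_box, bg_box


class TestAffineWindow:
    def test_identity_when_equal(self):
        x = np.arange(24.0).reshape(2, 3, 4)
        _, a, b = affine_window(x, x)
        assert (a, b) == (pytest.approx(1.0), pytest.approx(0.0, abs=1e-12))

    def test_closed_form_inverse_map(self):
        ref = np.arange(24.0).reshape(2, 3, 4)
        x = 2.0 * ref + 3.0
        _, a, b = affine_window(x, ref)
        assert a == pytest.approx(0.5)
        assert b == pytest.approx(-1.5)

    def test_windowing_never_hurts_rmse(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            ref = rng.normal(size=(5, 5, 5))
            x = rng.normal(size=(5, 5, 5)) + 2.0 * ref
            w, _, _ = affine_window(x, ref)
            assert rmse(w, ref) <= rmse(x, ref) + 1e-12

    def test_constant_input_warns(self):
        ref = np.arange(8.0).reshape(2, 2, 2)
        with pytest.warns(UserWarning, match="constant"):
            _, a, b = affine_window(np.ones((2, 2, 2)), ref)
        assert (a, b) == (1.0, 0.0)


class TestCnr:
    def test_hand_computed(self):
        arr, fg, bg = _vol_with([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])
        assert cnr(arr, fg, bg) == pytest.approx(3.0)  # (5-2)/sd{1,2,3}=3/1

    def test_equal_regions_zero(self):
        arr, fg, bg = _vol_with([2.0, 3.0, 4.0], [2.0, 3.0, 4.0])
        assert cnr(arr, fg, bg) == pytest.approx(0.0)

    def test_zero_background_sd_rejected(self):
        arr, fg, bg = _vol_with([5.0, 5.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            cnr(arr, fg, bg)

    def test_known_noise_level(self, gt4d, rois, phantom):
        """GT phantom plus N(0, sigma) noise: CNR ~ (mu_liver-mu_lung)/sigma."""
        sigma = 0.001
        rng = np.random.default_rng(0)
        noisy = gt4d[0].values + rng.normal(0.0, sigma, gt4d[0].values.shape)
        expect = (phantom.config.mu_liver - phantom.config.mu_lung) / sigma
        got = cnr(noisy, rois.cnr_foreground, rois.cnr_background)
        assert got == pytest.approx(expect, rel=0.35)  # small bg sample

    @given(a=st.floats(0.1, 50.0), b=st.floats(-10.0, 10.0))
    def test_invariant_under_global_affine(self, a, b):
        arr, fg, bg = _vol_with([5.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert cnr(a * arr + b, fg, bg) == pytest.approx(cnr(arr, fg, bg))


def _logistic_runs(k, l=40, n_runs=25):
    z = np.arange(l, dtype=float)
    f = 1.0 / (1.0 + np.exp(-k * (z - l / 2)))
    return np.tile(f, (n_runs, 1)).reshape(5, 5, l)


class TestTisTiw:
    def test_recovers_logistic_rate(self):
        box = _logistic_runs(0.5)
        got = tis(box, None)
        assert got == pytest.approx(0.5, rel=0.01)

    def test_hard_step_hits_sharpness_bound(self):
        box = np.zeros((5, 5, 20))
        box[:, :, 10:] = 1.0
        assert tis(box, None) >= K_MAX - 1e-6

    def test_descending_runs_flipped(self):
        box = _logistic_runs(0.5)[:, :, ::-1]
        assert tis(box, None) == pytest.approx(0.5, rel=0.01)

    def test_pure_noise_runs_excluded(self):
        rng = np.random.default_rng(1)
        box = _logistic_runs(0.5)
        box[0, :2] = rng.random((2, 40))  # 2 of 25 runs carry no edge
        assert tis(box, None) == pytest.approx(0.5, rel=0.02)

    def test_mostly_noise_rejected(self):
        rng = np.random.default_rng(2)
        box = rng.random((5, 5, 40))
        with pytest.raises(ValueError, match="fail"):
            tis(box, None)

    def test_tiw_arithmetic(self):
        assert tiw(1.0, 1.0) == pytest.approx(2.0 * math.log(9.0))
        assert tiw(2.0 * math.log(9.0) / 10.0, 1.0) == pytest.approx(10.0)

    def test_tiw_matches_logistic_crossing_distance(self):
        """TIW equals the 10-90% crossing distance of the fitted sigmoid."""
        k, w = 0.5, 1.0
        width = tiw(tis(_logistic_runs(k), None), w)
        # analytic crossings of 1/(1+exp(-k z)): z = +-ln(9)/k
        assert width == pytest.approx(2.0 * math.log(9.0) / k, rel=0.01)

    def test_nonpositive_tis_rejected(self):
        with pytest.raises(ValueError):
            tiw(0.0, 1.0)

    def test_blur_increases_tiw(self, gt4d, rois, grid):
        base = gt4d[0].values.astype(np.float64)
        widths = []
        for sig in (0.0, 1.0, 2.0, 3.0):
            img = ndimage.gaussian_filter(base, sig) if sig else base
            widths.append(tiw(tis(img, rois.tiw_box), grid.spacing[2]))
        assert widths == sorted(widths)


class TestRmse:
    def test_identical(self):
        x = np.random.default_rng(0).random((4, 4, 4))
        assert rmse(x, x) == 0.0

    def test_hand_computed(self):
        assert rmse(np.array([[[3.0, 4.0]]]),
                    np.array([[[0.0, 0.0]]])) == pytest.approx(
            math.sqrt(12.5))

    def test_matches_bruteforce_loop(self):
        rng = np.random.default_rng(5)
        x = rng.random((6, 5, 4))
        y = rng.random((6, 5, 4))
        acc = 0.0
        n = 0
        for i in range(6):
            for j in range(5):
                for k in range(4):
                    acc += (y[i, j, k] - x[i, j, k]) ** 2
                    n += 1
        assert rmse(x, y) == pytest.approx(math.sqrt(acc / n), abs=1e-10)


class TestSsim:
    def test_identical_is_one(self):
        x = np.random.default_rng(0).random((4, 4, 4))
        assert ssim(x, x) == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(1)
        x = rng.random((5, 5, 5))
        y = -x + 1.7  # anti-correlated with matched variance
        L = max(x.max(), y.max()) - min(x.min(), y.min())
        c1, c2 = (0.01 * L) ** 2, (0.03 * L) ** 2
        mx, my = x.mean(), y.mean()
        cov = np.cov(x.ravel(), y.ravel())[0, 1]
        expect = ((2 * mx * my + c1) * (2 * cov + c2)
                  / ((mx ** 2 + my ** 2 + c1)
                     * (x.var(ddof=1) + y.var(ddof=1) + c2)))
        got = ssim(x, y)
        assert got == pytest.approx(expect, abs=1e-12)
        assert got < 1.0 and (got < 0) == (cov < 0)

    def test_noise_monotonically_degrades(self, gt4d, rois):
        base = gt4d[0].values.astype(np.float64)
        L = base.max() - base.min()
        rng = np.random.default_rng(2)
        noise = rng.normal(size=base.shape)
        vals = [ssim(base + f * 0.01 * L * noise, base, rois.similarity_box)
                for f in (1.0, 2.0, 4.0)]
        assert vals[0] > vals[1] > vals[2]

    def test_symmetric(self):
        rng = np.random.default_rng(3)
        x = rng.random((4, 4, 4))
        y = rng.random((4, 4, 4))
        assert ssim(x, y) == pytest.approx(ssim(y, x), abs=1e-12)


class TestPhaseAverage:
    def test_identical_values(self):
        pa = phase_average([3.2] * 10)
        assert (pa.value, pa.n) == (pytest.approx(3.2), 10)

    def test_excluded_phase_dropped(self):
        vals = [1.0] * 9 + [float("nan")]
        pa = phase_average(vals)
        assert (pa.value, pa.n) == (pytest.approx(1.0), 9)

    def test_matches_manual_mean(self):
        vals = [1.0, 2.0, 4.0, 8.0]
        assert phase_average(vals).value == pytest.approx(np.mean(vals))


class TestPairedTTest:
    def test_matches_scipy_oracle(self):
        a = np.array([3.1, 2.7, 4.0, 3.3])
        b = np.array([2.9, 2.9, 3.1, 3.0])
        res = paired_t_test(a, b)
        oracle = stats.ttest_rel(a, b)
        assert res.t == pytest.approx(oracle.statistic, abs=1e-6)
        assert res.p == pytest.approx(oracle.pvalue, abs=1e-6)

    def test_null_calibration(self):
        """Under the null, ~5% of p-values fall below 0.05."""
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(200):
            eps = rng.normal(size=8)
            base = rng.normal(size=8)
            if paired_t_test(base + eps, base).p < 0.05:
                hits += 1
        assert 0.01 <= hits / 200 <= 0.09

    def test_constant_difference_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            paired_t_test([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0, 2.0], [0.0, 1.0])
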