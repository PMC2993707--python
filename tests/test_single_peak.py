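import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bigauss import (
    BiGaussianPeak,
    IonTrace,
    compute_A_hat,
    compute_B_hat,
    estimate_delta,
    estimate_sigmas,
    estimate_summit,
    evaluate_bigaussian,
    fit_single_peak,
)
from bigauss.single_peak import InsufficientDataError, UndefinedSplitError


class TestStepSizes:
    def test_three_case_rule(self):
        tr = IonTrace([0.0, 1.0, 3.0, 4.0], [1, 1, 1, 1])
        np.testing.assert_allclose(tr.step_sizes, [1.0, 1.5, 1.5, 1.0])

    def test_uniform_grid(self):
        tr = IonTrace([0, 1, 2], [1, 1, 1])
        np.testing.assert_allclose(tr.step_sizes, [1, 1, 1])


class TestSplitStatistics:
    def test_A_hat_hand_sum(self):
        # left of 1.5: two unit points; right: one -> log(2) - log(1)
        tr = IonTrace([0, 1, 2], [1.0, 1.0, 1.0])
        assert compute_A_hat(tr, 1.5) == pytest.approx(math.log(2))

    def test_A_hat_symmetric_is_zero(self):
        tr = IonTrace([0, 1, 2, 3], [1.0, 4.0, 4.0, 1.0])
        assert compute_A_hat(tr, 1.5) == pytest.approx(0.0)

    def test_B_hat_symmetric_is_zero(self):
        tr = IonTrace([0, 1, 2, 3], [1.0, 1.0, 1.0, 1.0])
        assert compute_B_hat(tr, 1.5) == pytest.approx(0.0)

    @pytest.mark.parametrize("ratio", [1 / 3, 1.0, 3.0])
    def test_both_equal_log_sigma_ratio_at_summit(self, ratio, dense_trace):
        peak = BiGaussianPeak(10, 1.0, 1.0 / ratio, 1e4)
        tr = dense_trace(peak, n=4000)
        expected = math.log(peak.sigma1 / peak.sigma2)
        assert compute_A_hat(tr, peak.alpha) == pytest.approx(expected, abs=5e-3)
        assert compute_B_hat(tr, peak.alpha) == pytest.approx(expected, abs=5e-3)

    def test_undefined_split_outside_range(self):
        tr = IonTrace([0, 1, 2], [1.0, 1.0, 1.0])
        with pytest.raises(UndefinedSplitError):
            compute_A_hat(tr, -5.0)
        with pytest.raises(UndefinedSplitError):
            compute_B_hat(tr, 10.0)


class TestSummit:
    @pytest.mark.parametrize("sigma2", [1.0, 3.0])
    def test_dense_noiseless_recovery(self, sigma2, dense_trace):
        peak = BiGaussianPeak(10, 1.0, sigma2, 1e4)
        tr = dense_trace(peak, n=500)
        step = tr.times[1] - tr.times[0]
        assert abs(estimate_summit(tr) - peak.alpha) < step

    def test_too_sparse_raises(self):
        with pytest.raises(InsufficientDataError):
            estimate_summit(IonTrace([0, 1], [1.0, 1.0]))

    def test_noisy_median_bias_below_grid_step(self):
        """100 replicates of multiplicative noise at xi=0.2, n=100."""
        peak = BiGaussianPeak(10, 1, 2, 1e4)
        t = np.linspace(4, 22, 100)
        clean = evaluate_bigaussian(peak, t)
        biases = []
        for rep in range(100):
            rng = np.random.default_rng((7, rep))
            x = clean * np.exp(rng.normal(0, 0.2, t.size))
            biases.append(estimate_summit(IonTrace(t, x)) - peak.alpha)
        assert np.median(np.abs(biases)) < t[1] - t[0]


class TestSigmas:
    def test_single_point_each_side(self):
        tr = IonTrace([-1.0, 1.0], [1.0, 1.0])
        s1, s2 = estimate_sigmas(tr, 0.0)
        assert s1 == pytest.approx(1.0)
        assert s2 == pytest.approx(1.0)

    @pytest.mark.parametrize("s1, s2, tol", [(1.0, 1.0, 0.02), (0.5, 1.5, 0.03)])
    def test_dense_noiseless_recovery(self, s1, s2, tol, dense_trace):
        peak = BiGaussianPeak(10, s1, s2, 1e4)
        tr = dense_trace(peak, n=500)
        e1, e2 = estimate_sigmas(tr, peak.alpha)
        assert e1 == pytest.approx(s1, rel=tol)
        assert e2 == pytest.approx(s2, rel=tol)

    def test_one_sided_mirrors(self):
        # all mass right of the proposed summit: left mirrors right
        tr = IonTrace([1.0, 2.0, 3.0], [1.0, 2.0, 1.0])
        s1, s2 = estimate_sigmas(tr, 0.5)
        assert s1 == s2


class TestDelta:
    def test_exact_data_recovers_delta(self, dense_trace):
        peak = BiGaussianPeak(10, 1, 2, 1e4)
        t = np.linspace(4, 22, 100)
        tr = IonTrace(t, evaluate_bigaussian(peak, t))
        d = estimate_delta(tr, peak.alpha, peak.sigma1, peak.sigma2)
        assert d == pytest.approx(1e4, rel=1e-3)

    def test_scaling_covariance(self):
        peak = BiGaussianPeak(10, 1, 2, 1e4)
        t = np.linspace(4, 22, 100)
        x = evaluate_bigaussian(peak, t)
        d1 = estimate_delta(IonTrace(t, x), 10, 1, 2)
        d2 = estimate_delta(IonTrace(t, 3.5 * x), 10, 1, 2)
        assert d2 == pytest.approx(3.5 * d1, rel=1e-12)

    def test_zeros_are_ignored(self):
        peak = BiGaussianPeak(10, 1, 2, 1e4)
        t = np.linspace(4, 22, 100)
        x = evaluate_bigaussian(peak, t)
        x_holes = x.copy()
        x_holes[::3] = 0.0
        d_full = estimate_delta(IonTrace(t, x), 10, 1, 2)
        d_holes = estimate_delta(IonTrace(t, x_holes), 10, 1, 2)
        assert d_holes == pytest.approx(d_full, rel=1e-9)


class TestFitSinglePeak:
    def test_round_trip(self, dense_trace):
        peak = BiGaussianPeak(12, 0.8, 1.6, 5e4)
        fit = fit_single_peak(dense_trace(peak, n=500))
        for name in ("alpha", "sigma1", "sigma2", "delta"):
            assert getattr(fit, name) == pytest.approx(getattr(peak, name), rel=0.03)

    def test_symmetric_input_balanced_sigmas(self, dense_trace):
        fit = fit_single_peak(dense_trace(BiGaussianPeak(5, 1, 1, 1e3), n=500))
        assert abs(fit.sigma1 / fit.sigma2 - 1) < 0.05


@settings(max_examples=25, deadline=None)
@given(shift=st.floats(-100, 100), scale=st.floats(0.01, 1e4))
def test_shift_and_scale_equivariance(shift, scale):
    """Shifting time moves alpha; scaling intensity scales delta only."""
    peak = BiGaussianPeak(10, 1, 2, 1e4)
    t = np.linspace(4, 22, 200)
    x = evaluate_bigaussian(peak, t)
    base = fit_single_peak(IonTrace(t, x))
    moved = fit_single_peak(IonTrace(t + shift, scale * x))
    assert moved.alpha == pytest.approx(base.alpha + shift, abs=1e-6 * max(1, abs(shift)) + 1e-6)
    assert moved.sigma1 == pytest.approx(base.sigma1, rel=1e-9)
    assert moved.sigma2 == pytest.approx(base.sigma2, rel=1e-9)
    assert moved.delta == pytest.approx(scale * base.delta, rel=1e-9)
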