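import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from nmachart import (
    MovingAverageChart,
    control_limits,
    monitor,
    moving_average_series,
    transform_time,
)

# Frozen from direct gamma-function arithmetic of the limit formulas.
EXPECTED_LCL = 0.6813605284049915
EXPECTED_UCL = 1.1208508381595876


class TestMovingAverageSeries:
    def test_betaine_lower_w3_index5(self, betaine):
        means = transform_time(betaine.lower).mean(axis=1)
        ma = moving_average_series(means, 3)
        assert round(ma[4], 2) == 3.66  # mean of published 4.16, 3.23, 3.58

    def test_betaine_upper_w5_index6(self, betaine):
        means = transform_time(betaine.upper).mean(axis=1)
        ma = moving_average_series(means, 5)
        assert round(ma[5], 1) == 4.3

    def test_w1_is_identity(self, rng):
        x = rng.normal(size=20)
        np.testing.assert_array_equal(moving_average_series(x, 1), x)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            moving_average_series([1.0, 2.0], 0)
        with pytest.raises(ValueError):
            moving_average_series([], 3)

    @given(
        x=st.lists(st.floats(-100, 100), min_size=1, max_size=30),
        shift=st.floats(-50, 50),
        w=st.integers(1, 6),
    )
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_translation_equivariance(self, x, shift, w):
        base = moving_average_series(x, w)
        moved = moving_average_series(np.asarray(x) + shift, w)
        np.testing.assert_allclose(moved, base + shift, atol=1e-9)

    @given(const=st.floats(-10, 10), m=st.integers(1, 20), w=st.integers(1, 8))
    @settings(deadline=None, derandomize=True, max_examples=40)
    def test_constant_input_fixed_point(self, const, m, w):
        out = moving_average_series(np.full(m, const), w)
        np.testing.assert_allclose(out, const, atol=1e-12)


class TestControlLimits:
    def test_derived_example(self):
        lims = control_limits(1.0, 4, 3, 2.738)
        assert lims.lcl == pytest.approx(EXPECTED_LCL, rel=1e-12)
        assert lims.ucl == pytest.approx(EXPECTED_UCL, rel=1e-12)
        assert lims.lcl + lims.ucl == pytest.approx(2 * lims.center, rel=1e-12)

    def test_k_zero_collapses_to_center(self):
        lims = control_limits(10.0, 4, 3, 0.0)
        assert lims.lcl == lims.center == lims.ucl

    def test_half_width_linear_in_k(self):
        h1 = control_limits(1.0, 4, 3, 1.3).half_width
        h2 = control_limits(1.0, 4, 3, 2.6).half_width
        assert h2 == pytest.approx(2 * h1, rel=1e-12)

    @pytest.mark.parametrize("grid", [[1, 2, 4, 8]])
    def test_half_width_strictly_decreasing_in_n_and_w(self, grid):
        widths_n = [control_limits(1.0, n, 3, 2.7).half_width for n in grid]
        widths_w = [control_limits(1.0, 4, w, 2.7).half_width for w in grid]
        assert all(a > b for a, b in zip(widths_n, widths_n[1:]))
        assert all(a > b for a, b in zip(widths_w, widths_w[1:]))

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(theta0=-1.0, n=4, w=3, k=2.7),
            dict(theta0=1.0, n=0, w=3, k=2.7),
            dict(theta0=1.0, n=4, w=0, k=2.7),
            dict(theta0=1.0, n=4, w=3, k=-0.1),
        ],
    )
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ValueError):
            control_limits(**kwargs)


class TestMonitor:
    def test_all_inside_yields_no_signal(self):
        lims = control_limits(1.0, 4, 3, 2.738)
        res = monitor(np.full(10, lims.center), lims)
        assert res.first_signal is None
        assert not res.out_of_control.any()

    def test_constructed_signal_at_index_two(self):
        lims = control_limits(1.0, 4, 3, 2.738)
        res = monitor([lims.center, lims.ucl + 1.0], lims)
        assert res.first_signal == 2
        assert res.flags == ["in", "out"]

    def test_boundary_values_count_in_control(self):
        lims = control_limits(1.0, 4, 3, 2.738)
        res = monitor([lims.lcl, lims.ucl], lims)
        assert res.first_signal is None

    def test_start_skips_warmup_points(self):
        lims = control_limits(1.0, 4, 3, 2.738)
        res = monitor([lims.ucl + 1.0, lims.center, lims.ucl + 1.0], lims, start=3)
        assert res.first_signal == 3


class TestMovingAverageChartEstimator:
    def test_betaine_lower_in_control(self, betaine):
        chart = MovingAverageChart(window=3, k=2.95, theta0=1 / 0.0042)
        res = chart.fit(betaine.lower).monitor(betaine.lower)
        assert res.first_signal is None

    def test_predict_uses_outlier_convention(self, betaine):
        chart = MovingAverageChart(window=3, k=2.95, theta0=1 / 0.0042)
        pred = chart.fit_predict(betaine.lower)
        assert set(pred) <= {-1, 1}
        assert pred.shape == (betaine.m,)

    def test_theta0_estimated_from_fit_data_when_absent(self, betaine):
        chart = MovingAverageChart(window=3, k=2.95).fit(betaine.lower)
        assert chart.theta0_ == pytest.approx(betaine.lower.mean())

    def test_sklearn_params_round_trip(self):
        chart = MovingAverageChart(window=5, k=2.89, theta0=131.6)
        cloned = clone(chart)
        assert cloned.get_params() == chart.get_params()
        cloned.set_params(k=3.0)
        assert cloned.k == 3.0 and chart.k == 2.89

    def test_rejects_negative_times_and_wrong_ndim(self):
        chart = MovingAverageChart()
        with pytest.raises(ValueError):
            chart.fit(np.array([[1.0, -2.0]]))
        with pytest.raises(ValueError):
            chart.fit(np.ones(5))

    def test_evaluate_partial_flags_head_points(self, betaine):
        # the head of the upper Betaine series sits far above the fixed-theta0
        # limits, but only the partial-window mode evaluates it
        full = MovingAverageChart(window=5, k=2.89, theta0=1 / 0.0076)
        partial = clone(full).set_params(evaluate_partial=True)
        assert full.fit(betaine.upper).monitor(betaine.upper).first_signal == 5
        assert partial.fit(betaine.upper).monitor(betaine.upper).first_signal == 1
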