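"""Calibration, Eq.-1 conversion, interpolation, AUC/HI, first-order fitting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from egikit import (
    DegenerateDesignError,
    DomainError,
    ExtrapolationError,
    GlucoseCalibration,
    SimulationConfig,
    auc_trapezoid,
    first_order_curve,
    fit_first_order,
    fit_glucose_calibration,
    glucose_from_absorbance,
    hydrolysis_index,
    simulate_curve,
    starch_hydrolysis_pct,
    value_at,
)
from egikit.io import INTESTINAL_GRID

from conftest import make_curve

grid_values = st.lists(
    st.floats(0, 100, allow_nan=False), min_size=7, max_size=7
)


class TestGlucoseCalibration:
    def test_two_point_exact_line(self):
        cal = fit_glucose_calibration([(0, 0.00), (1, 0.80)])
        assert cal.slope == pytest.approx(0.80)
        assert cal.intercept == pytest.approx(0.0, abs=1e-12)
        assert cal.r_squared == pytest.approx(1.0)

    def test_collinear_three_points(self):
        cal = fit_glucose_calibration([(0, 0.02), (0.5, 0.42), (1, 0.82)])
        assert cal.slope == pytest.approx(0.80)
        assert cal.intercept == pytest.approx(0.02)
        assert cal.r_squared == pytest.approx(1.0)

    def test_identical_concentrations_rejected(self):
        with pytest.raises(DegenerateDesignError):
            fit_glucose_calibration([(0.5, 0.4), (0.5, 0.5)])

    def test_inversion(self):
        cal = GlucoseCalibration(slope=0.80, intercept=0.0, r_squared=1.0)
        assert glucose_from_absorbance(cal.intercept, cal) == 0.0
        assert glucose_from_absorbance(0.40, cal) == pytest.approx(0.50)
        assert glucose_from_absorbance(0.40, cal, dilution=4) == pytest.approx(2.00)

    def test_negative_concentration_clipped(self):
        cal = GlucoseCalibration(slope=0.80, intercept=0.10, r_squared=1.0)
        with pytest.warns(UserWarning, match="clipped"):
            assert glucose_from_absorbance(0.05, cal) == 0.0


class TestStarchHydrolysisPct:
    @pytest.mark.parametrize(
        "g_t, ts, expected",
        [(0.0, 1.0, 0.0), (1.0 / 0.9, 1.0, 100.0), (0.5, 0.9, 50.0)],
    )
    def test_examples(self, g_t, ts, expected):
        assert starch_hydrolysis_pct(g_t, ts) == pytest.approx(expected)

    def test_nonpositive_starch_rejected(self):
        with pytest.raises(DomainError):
            starch_hydrolysis_pct(1.0, 0.0)

    @given(
        g=st.floats(0, 10, allow_nan=False),
        ts=st.floats(0.1, 10, allow_nan=False),
        lam=st.floats(0.1, 5, allow_nan=False),
    )
    def test_linear_in_glucose_inverse_linear_in_starch(self, g, ts, lam):
        base = starch_hydrolysis_pct(g, ts)
        assert starch_hydrolysis_pct(lam * g, ts) == pytest.approx(lam * base)
        assert starch_hydrolysis_pct(g, lam * ts) == pytest.approx(base / lam)


class TestValueAt:
    def test_midpoint_of_line(self):
        c = make_curve([10, 90], times=[0, 120])
        assert value_at(c, 60) == pytest.approx(50)

    def test_on_grid_identity(self):
        c = make_curve([5, 40, 73.4, 90], times=[0, 60, 90, 120])
        assert value_at(c, 90) == 73.4

    def test_no_extrapolation(self):
        c = make_curve([0, 100], times=[0, 120])
        with pytest.raises(ExtrapolationError):
            value_at(c, 150)

    @given(values=grid_values, frac=st.floats(0, 1, allow_nan=False))
    def test_interpolant_bounded_by_bracketing_samples(self, values, frac):
        c = make_curve(values)
        t = np.asarray(c.times)
        i = 3
        tt = t[i] + frac * (t[i + 1] - t[i])
        lo = min(c.values[i], c.values[i + 1])
        hi = max(c.values[i], c.values[i + 1])
        assert lo - 1e-9 <= value_at(c, tt) <= hi + 1e-9


def segmentwise_integral(times, values, a, b):
    """Independent AUC oracle: exact antiderivative of each linear segment."""
    total = 0.0
    for (t1, t2, v1, v2) in zip(times, times[1:], values, values[1:]):
        lo, hi = max(t1, a), min(t2, b)
        if hi <= lo:
            continue
        m = (v2 - v1) / (t2 - t1)
        c = v1 - m * t1
        total += m / 2 * (hi**2 - lo**2) + c * (hi - lo)
    return total


class TestAuc:
    def test_constant_curve(self, constant_curve):
        assert auc_trapezoid(constant_curve, 0, 120) == pytest.approx(12000)

    def test_linear_curve(self, linear_curve):
        assert auc_trapezoid(linear_curve, 0, 120) == pytest.approx(6000)

    def test_zero_width_window_rejected(self, linear_curve):
        with pytest.raises(ValueError):
            auc_trapezoid(linear_curve, 60, 60)

    @given(
        values=grid_values,
        a=st.floats(0, 119, allow_nan=False),
        width=st.floats(0.5, 120, allow_nan=False),
    )
    def test_matches_segmentwise_closed_form(self, values, a, width):
        b = min(a + width, 120.0)
        c = make_curve(values)
        oracle = segmentwise_integral(c.times, c.values, a, b)
        assert auc_trapezoid(c, a, b) == pytest.approx(oracle, abs=1e-8)


class TestHydrolysisIndex:
    def test_constant_100_is_100(self, constant_curve):
        assert hydrolysis_index(constant_curve) == pytest.approx(100)

    def test_linear_is_50(self, linear_curve):
        assert hydrolysis_index(linear_curve) == pytest.approx(50)

    def test_all_zero_is_0(self):
        c = make_curve([0] * 7)
        assert hydrolysis_index(c) == 0.0

    def test_explicit_reference(self, linear_curve, constant_curve):
        assert hydrolysis_index(linear_curve, reference=constant_curve) == pytest.approx(50)

    def test_zero_reference_rejected(self, linear_curve):
        zero = make_curve([0] * 7)
        with pytest.raises(DomainError):
            hydrolysis_index(linear_curve, reference=zero)

    @given(values=grid_values, lam=st.floats(0.01, 1, allow_nan=False))
    def test_scale_invariance(self, values, lam):
        c = make_curve(values)
        scaled = make_curve([v * lam for v in values])
        assert hydrolysis_index(scaled) == pytest.approx(lam * hydrolysis_index(c))


class TestFirstOrderFit:
    def test_noiseless_recovery(self):
        t = np.asarray(INTESTINAL_GRID)
        c = make_curve(first_order_curve(t, 10, 95, 0.03))
        fit = fit_first_order(c)
        assert fit.c0 == pytest.approx(10, rel=1e-6)
        assert fit.c_inf == pytest.approx(95, rel=1e-6)
        assert fit.k == pytest.approx(0.03, rel=1e-6)
        assert fit.rss < 1e-12

    def test_constant_curve_flagged_indeterminate(self):
        fit = fit_first_order(make_curve([40.0] * 7))
        assert fit.c0 == fit.c_inf == 40.0
        assert fit.k == 0.0
        assert "k_indeterminate" in fit.flags

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_first_order(make_curve([0, 50, 100], times=[0, 60, 120]))

    def test_short_span_rejected(self):
        with pytest.raises(ValueError):
            fit_first_order(make_curve([0, 10, 20, 30], times=[0, 10, 20, 30]))

    def test_noisy_k_recovery(self):
        # Monte-Carlo over the seeded simulator: 200 replicates at 2 % noise
        cfg = SimulationConfig(seed=123, c0=10, c_inf=95, k=0.03, noise_sd=2.0,
                               n_replicates=200)
        curves = simulate_curve(cfg, "mc")
        errs = [abs(fit_first_order(c).k - 0.03) for c in curves]
        assert np.mean(errs) < 0.005
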