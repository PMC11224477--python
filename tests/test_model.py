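"""Logistic model, empirical rates, phase partition, quadratic peak."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from grainfill import (
    DataValidationError,
    DegenerateFitError,
    DegeneratePartitionError,
    InvalidParameterError,
    K1_TRUNCATED,
    LogisticParams,
    empirical_rate_series,
    logistic_acceleration,
    logistic_rate,
    logistic_weight,
    partition_phases,
    phase_offsets,
    quadratic_peak,
)

from conftest import random_valid_params

valid_params = st.builds(
    LogisticParams,
    A=st.floats(1.0, 100.0),
    B=st.floats(5.0, 200.0),
    C=st.floats(0.05, 0.5),
)


class TestLogisticWeight:
    @pytest.mark.parametrize(
        "t, expected",
        [
            (math.log(40.0) / 0.15, 15.0),    # half the asymptote at lnB/C
            (0.0, 30.0 / 41.0),               # flowering-day weight A/(1+B)
            (10_000.0, 30.0),                 # asymptote
        ],
    )
    def test_reference_values(self, ref_params, t, expected):
        assert logistic_weight(ref_params, t) == pytest.approx(expected, abs=1e-9)

    def test_invalid_parameters_rejected(self):
        for bad in [(-1, 40, 0.15), (30, 0, 0.15), (30, 40, -0.1), (np.nan, 40, 0.15)]:
            with pytest.raises(InvalidParameterError):
                LogisticParams(*bad)

    @given(p=valid_params)
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_bounded(self, p):
        t = np.linspace(-10, 120, 200)
        w = logistic_weight(p, t)
        assert np.all(np.diff(w) >= 0)
        # strictly increasing wherever the curve is not float-saturated
        live = w[:-1] < p.A * (1 - 1e-12)
        assert np.all(np.diff(w)[live] > 0)
        assert np.all(w > 0) and np.all(w <= p.A)


class TestLogisticRate:
    def test_peak_rate_is_AC_over_4(self, ref_params):
        t_peak = math.log(40.0) / 0.15
        assert logistic_rate(ref_params, t_peak) == pytest.approx(1.125, rel=1e-12)

    def test_value_at_zero(self, ref_params):
        # A*B*C / (1+B)^2 evaluated directly
        assert logistic_rate(ref_params, 0.0) == pytest.approx(
            30 * 40 * 0.15 / 41**2, rel=1e-12
        )

    @given(p=valid_params, t=st.floats(0.0, 80.0))
    @settings(max_examples=50, deadline=None)
    def test_matches_finite_difference(self, p, t):
        h = 1e-5
        fd = (logistic_weight(p, t + h) - logistic_weight(p, t - h)) / (2 * h)
        assert logistic_rate(p, t) == pytest.approx(fd, rel=1e-4, abs=1e-9)

    @given(p=valid_params, t=st.floats(0.0, 80.0))
    @settings(max_examples=50, deadline=None)
    def test_acceleration_matches_finite_difference(self, p, t):
        h = 1e-4
        fd = (logistic_rate(p, t + h) - logistic_rate(p, t - h)) / (2 * h)
        assert logistic_acceleration(p, t) == pytest.approx(fd, rel=1e-5, abs=1e-8)


class TestEmpiricalRates:
    def test_single_interval(self):
        (pt,) = empirical_rate_series([15.0, 20.0], [7.0, 12.0])
        assert pt.rate == pytest.approx(1.0)
        assert pt.t_mid == pytest.approx(17.5)
        assert not pt.decreasing

    def test_constant_weights_zero_rate(self):
        pts = empirical_rate_series([15, 20, 25], [5.0, 5.0, 5.0])
        assert [p.rate for p in pts] == [0.0, 0.0]

    def test_rates_close_to_analytic_curve(self, ref_params):
        dap = np.arange(15.0, 50.0, 5.0)
        w = logistic_weight(ref_params, dap)
        for pt in empirical_rate_series(dap, w):
            assert pt.rate == pytest.approx(
                logistic_rate(ref_params, pt.t_mid), rel=0.02
            )

    def test_duplicate_dap_rejected(self):
        with pytest.raises(DataValidationError):
            empirical_rate_series([15, 15, 20], [5, 6, 7])

    def test_decreasing_weight_flagged_not_dropped(self):
        with pytest.warns(UserWarning, match="decreasing"):
            pts = empirical_rate_series([15, 20, 25], [7.0, 6.0, 9.0])
        assert pts[0].decreasing and pts[0].rate < 0
        assert len(pts) == 2


class TestPartition:
    def test_reference_partition(self, ref_params):
        ph = partition_phases(ref_params)
        # frozen from direct closed-form evaluation with the truncated
        # 1.317 / 4.59512 offsets
        assert ph.t1 == pytest.approx(15.81253, abs=1e-4)
        assert ph.t2 == pytest.approx(33.37253, abs=1e-4)
        assert ph.t3 == pytest.approx(55.22666, abs=1e-4)
        assert ph.T2 == pytest.approx(17.56, abs=1e-3)
        assert ph.T3 == pytest.approx(21.85413, abs=1e-4)
        assert ph.W1 == pytest.approx(6.33954, abs=1e-4)
        assert ph.W2 == pytest.approx(23.66046, abs=1e-4)
        assert ph.V2 == pytest.approx(0.986385, abs=1e-5)
        assert ph.t_max == pytest.approx(math.log(40) / 0.15, rel=1e-12)
        assert ph.G_max == pytest.approx(1.125, rel=1e-12)

    def test_boundary_weight_fractions(self, ref_params):
        ph = partition_phases(ref_params, constants="exact")
        assert ph.W1 / ph.W0 == pytest.approx((1 + 40) / (3 + math.sqrt(3)), rel=1e-9)
        assert ph.W1 / 30 == pytest.approx(0.21132, abs=1e-4)
        assert ph.W2 / 30 == pytest.approx(0.78868, abs=1e-4)
        assert ph.W3 / 30 == pytest.approx(0.99, rel=1e-12)

    @pytest.mark.parametrize("constants", ["truncated", "exact"])
    @pytest.mark.parametrize("seed", [0, 1])
    def test_invariants_random_params(self, constants, seed):
        rng = np.random.default_rng(seed)
        for p in random_valid_params(rng, 50):
            ph = partition_phases(p, constants=constants)
            assert 0 < ph.t1 < ph.t_max < ph.t2 < ph.t3
            assert ph.t_max == pytest.approx((ph.t1 + ph.t2) / 2, rel=1e-12)
            assert ph.V2 > ph.V1 and ph.V2 > ph.V3
            assert ph.T3 > ph.T2
            # mass balance: gains telescope to 99% of A minus W0
            k3 = phase_offsets(constants)[1]
            w3_frac = 1.0 / (1.0 + math.exp(-k3))
            assert ph.w1 + ph.w2 + ph.w3 == pytest.approx(
                w3_frac * p.A - ph.W0, rel=1e-9
            )

    def test_forced_ratio_identities(self):
        rng = np.random.default_rng(42)
        ratios_v = set()
        ratios_t = set()
        for p in random_valid_params(rng, 100):
            ph = partition_phases(p)
            ratios_v.add(round(ph.V2 / ph.V3, 9))
            ratios_t.add(round(ph.T3 / ph.T2, 9))
        assert len(ratios_v) == 1 and len(ratios_t) == 1
        assert ratios_v.pop() == pytest.approx(3.5692, abs=1e-3)
        assert ratios_t.pop() == pytest.approx(1.2446, abs=1e-3)

    def test_scale_equivariance(self, ref_params):
        base = partition_phases(ref_params)
        k = 2.5
        scaled_a = partition_phases(LogisticParams(30 * k, 40, 0.15))
        for name in ("W0", "W1", "W2", "W3", "w1", "w2", "w3", "V1", "V2", "V3", "G_max"):
            assert getattr(scaled_a, name) == pytest.approx(
                k * getattr(base, name), rel=1e-12
            )
        for name in ("t1", "t2", "t3", "T1", "T2", "T3", "t_max"):
            assert getattr(scaled_a, name) == pytest.approx(
                getattr(base, name), rel=1e-12
            )
        scaled_c = partition_phases(LogisticParams(30, 40, 0.15 * k))
        for name in ("t1", "t2", "t3", "T1", "T2", "T3", "t_max"):
            assert getattr(scaled_c, name) == pytest.approx(
                getattr(base, name) / k, rel=1e-12
            )
        for name in ("V1", "V2", "V3", "G_max"):
            assert getattr(scaled_c, name) == pytest.approx(
                k * getattr(base, name), rel=1e-12
            )

    def test_degenerate_partition_error(self):
        with pytest.raises(DegeneratePartitionError):
            partition_phases(LogisticParams(1.0, math.exp(K1_TRUNCATED), 1.0))
        # just above the boundary: finite, t1 -> 0+
        eps = 1e-6
        ph = partition_phases(LogisticParams(1.0, math.exp(K1_TRUNCATED + eps), 1.0))
        assert 0 < ph.t1 < 1e-5
        assert np.isfinite(ph.V1)

    def test_numeric_root_oracle(self):
        """t1/t2 are the concavity changes of the rate curve; t3 solves
        W = 0.99 A — checked by bracketed root-finding."""
        rng = np.random.default_rng(7)
        for p in random_valid_params(rng, 20):
            ph = partition_phases(p, constants="exact")

            def d3w(t):
                h = 1e-3
                return (
                    logistic_acceleration(p, t + h) - logistic_acceleration(p, t - h)
                ) / (2 * h)

            t1 = brentq(d3w, 1e-9, p.t_max - 1e-9, xtol=1e-10)
            t2 = brentq(d3w, p.t_max + 1e-9, 10 * p.t_max, xtol=1e-10)
            t3 = brentq(
                lambda t: logistic_weight(p, t) - 0.99 * p.A,
                p.t_max, 100 * p.t_max, xtol=1e-10,
            )
            assert ph.t1 == pytest.approx(t1, abs=1e-6)
            assert ph.t2 == pytest.approx(t2, abs=1e-6)
            assert ph.t3 == pytest.approx(t3, abs=1e-6)


class TestQuadraticPeak:
    def test_exact_vertex_recovery(self):
        t = np.arange(15.0, 51.0, 5.0)
        r = -0.01 * (t - 30.0) ** 2 + 2.0
        x, y = quadratic_peak(list(zip(t, r)))
        assert x == pytest.approx(30.0, abs=1e-9)
        assert y == pytest.approx(2.0, abs=1e-9)

    def test_collinear_points_rejected(self):
        with pytest.raises(DegenerateFitError):
            quadratic_peak([(1, 1.0), (2, 2.0), (3, 3.0)])

    def test_too_few_points(self):
        with pytest.raises(DataValidationError):
            quadratic_peak([(1, 1.0), (2, 2.0)])

    def test_matches_independent_vertex_oracle(self, ref_params):
        """quadratic_peak returns exactly the vertex of the least-squares
        parabola, checked against an independent lstsq solve."""
        dap = np.arange(15.0, 51.0, 5.0)
        w = logistic_weight(ref_params, dap)
        pts = empirical_rate_series(dap, w)
        x, y = quadratic_peak(pts)
        t = np.array([p.t_mid for p in pts])
        r = np.array([p.rate for p in pts])
        X = np.column_stack([np.ones_like(t), t, t**2])
        a, b, c = np.linalg.lstsq(X, r, rcond=None)[0]
        assert x == pytest.approx(-b / (2 * c), rel=1e-9)
        assert y == pytest.approx(a - b**2 / (4 * c), rel=1e-9)

    def test_approximates_logistic_peak(self, ref_params):
        """The parabola is a coarse summary of the skewed rate curve: its
        vertex sits a few days before t_max and somewhat below G_max."""
        dap = np.arange(15.0, 51.0, 5.0)
        w = logistic_weight(ref_params, dap)
        x, y = quadratic_peak(empirical_rate_series(dap, w))
        assert x == pytest.approx(ref_params.t_max, abs=4.0)
        assert y == pytest.approx(ref_params.g_max, rel=0.15)
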