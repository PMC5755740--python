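"""Closed-form thermal response functions and derived quantities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenorisk import ThermalFunctionSpec, thermal

from oracles import brute_force_briere_argmax


def briere(a=1e-4, tmin=10.0, tmax=35.0):
    return ThermalFunctionSpec("briere1", {"a": a, "Tmin": tmin, "Tmax": tmax})


ROSA_EGG_MORT = ThermalFunctionSpec(
    "mortality_expquad", {"b1": 10.271, "b2": -0.909, "b3": 0.019}
)


class TestDevelopmentRate:
    @pytest.mark.parametrize("T,expected", [(10.0, 0.0), (35.0, 0.0), (5.0, 0.0),
                                            (40.0, 0.0)])
    def test_zero_outside_thresholds(self, T, expected):
        assert thermal.eval_development_rate(briere(), T) == expected

    def test_value_inside(self):
        # 1e-4 * 25 * 15 * sqrt(10)
        assert thermal.eval_development_rate(briere(), 25.0) == pytest.approx(
            0.11858541, rel=1e-6
        )

    def test_positive_on_open_interval(self):
        T = np.linspace(10.01, 34.99, 200)
        assert np.all(thermal.eval_development_rate(briere(), T) > 0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            thermal.eval_development_rate(briere(), np.nan)

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError):
            ThermalFunctionSpec("briere1", {"a": 1e-4, "Tmin": 0.0, "Tmax": 0.0})


class TestOptimumTemperature:
    def test_closed_form_value(self):
        assert thermal.optimum_temperature(briere()) == pytest.approx(29.2066, abs=1e-4)

    def test_matches_brute_force_argmax(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            tmin = rng.uniform(-5, 20)
            tmax = tmin + rng.uniform(5, 30)
            spec = briere(1e-4, tmin, tmax)
            topt = thermal.optimum_temperature(spec)
            assert tmin < topt < tmax
            assert abs(topt - brute_force_briere_argmax(1e-4, tmin, tmax)) < 0.01


class TestMortality:
    def test_printed_parameter_value(self):
        # exp(10.271 - 0.909*25 + 0.019*625) = exp(-0.579)
        assert thermal.eval_mortality(ROSA_EGG_MORT, 25.0) == pytest.approx(
            0.5605, abs=2e-4
        )

    def test_clipped_at_one(self):
        hot = thermal.eval_mortality(ROSA_EGG_MORT, 60.0)
        assert hot == 1.0

    def test_vanishing_limit(self):
        spec = ThermalFunctionSpec(
            "mortality_expquad", {"b1": -500.0, "b2": 0.0, "b3": 0.0}
        )
        assert thermal.eval_mortality(spec, 25.0) == pytest.approx(0.0, abs=1e-100)

    @given(
        b1=st.floats(-20, 20), b2=st.floats(-3, 3), b3=st.floats(-0.2, 0.2),
        T=st.floats(-40, 60),
    )
    @settings(max_examples=200, deadline=None)
    def test_always_in_unit_interval(self, b1, b2, b3, T):
        spec = ThermalFunctionSpec("mortality_expquad", {"b1": b1, "b2": b2, "b3": b3})
        m = thermal.eval_mortality(spec, T)
        assert 0.0 <= m <= 1.0

    def test_u_shape_minimum(self):
        tmin = -ROSA_EGG_MORT.params["b2"] / (2 * ROSA_EGG_MORT.params["b3"])
        T = np.linspace(tmin - 5, tmin + 5, 101)
        m = thermal.eval_mortality(ROSA_EGG_MORT, T)
        assert np.argmin(m) == 50


class TestSenescence:
    def test_printed_parameter_value(self):
        spec = ThermalFunctionSpec(
            "senescence_exponential", {"b1": 0.0098, "b2": 0.0403}
        )
        rate = thermal.eval_senescence(spec, 15.0)
        assert rate == pytest.approx(0.017937, abs=1e-6)
        assert 1.0 / rate == pytest.approx(55.8, abs=0.1)  # expected longevity

    def test_temperature_independent_limit(self):
        spec = ThermalFunctionSpec("senescence_exponential", {"b1": 0.01, "b2": 0.0})
        for T in (0.0, 20.0, 40.0):
            assert thermal.eval_senescence(spec, T) == 0.01

    def test_nonpositive_b1_rejected(self):
        with pytest.raises(ValueError):
            ThermalFunctionSpec("senescence_exponential", {"b1": -0.01, "b2": 0.1})

    def test_stinner_degenerates_to_single_logistic(self):
        full = ThermalFunctionSpec(
            "senescence_stinner",
            {"C1": 0.3, "C2": 0.0, "k1": 4.0, "k2": -0.2, "T0": 40.0},
        )
        T = np.linspace(5, 40, 50)
        expected = 0.3 / (1 + np.exp(4.0 - 0.2 * T))
        np.testing.assert_allclose(thermal.eval_senescence(full, T), expected)


class TestFecundity:
    ROSA = ThermalFunctionSpec(
        "fecundity_exppoly", {"b1": -7.851, "b2": 1.064, "b3": -0.019}
    )
    QUIL = ThermalFunctionSpec(
        "fecundity_gaussian",
        {"y0": -41393.36, "a": 41971.86, "b": 74.63, "x0": 25.126},
    )

    def test_exppoly_printed_value(self):
        assert thermal.eval_total_fecundity(self.ROSA, 25.0) == pytest.approx(
            966.9, rel=1e-3
        )

    def test_exppoly_argmax(self):
        # -b2/(2*b3) = 28.0; check numerically too
        T = np.linspace(20, 36, 1601)
        f = thermal.eval_total_fecundity(self.ROSA, T)
        assert T[np.argmax(f)] == pytest.approx(28.0, abs=0.01)

    def test_gaussian_peak_value(self):
        assert thermal.eval_total_fecundity(self.QUIL, 25.126) == pytest.approx(
            578.50, abs=0.01
        )

    def test_gaussian_negative_tail_floored(self):
        assert thermal.eval_total_fecundity(self.QUIL, -100.0) == 0.0


class TestOvipositionCdf:
    GAMMA = ThermalFunctionSpec("ovip_gamma", {"a": 3.404, "b": 3.906})
    LOGISTIC = ThermalFunctionSpec("ovip_logistic", {"a": 3.94859, "b": -3.43037})

    def test_gamma_at_origin(self):
        assert thermal.eval_oviposition_cdf(self.GAMMA, 0.0) == 0.0

    def test_logistic_median(self):
        x50 = thermal.oviposition_median_age(self.LOGISTIC)
        assert x50 == pytest.approx(1.1511, abs=1e-4)
        assert thermal.eval_oviposition_cdf(self.LOGISTIC, x50) == pytest.approx(0.5)

    def test_gamma_mean_by_numerical_integration(self):
        # mean of the implied density = shape/rate, cross-checked by
        # integrating x dO numerically
        x = np.linspace(0, 30, 300001)
        o = thermal.eval_oviposition_cdf(self.GAMMA, x)
        mean = float(np.sum(0.5 * (x[1:] + x[:-1]) * np.diff(o)))
        assert mean == pytest.approx(3.404 / 3.906, abs=1e-3)
        assert mean == pytest.approx(0.8715, abs=1e-3)

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            thermal.eval_oviposition_cdf(self.GAMMA, -0.1)

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ValueError):
            ThermalFunctionSpec("ovip_gamma", {"a": -1.0, "b": 2.0})

    @pytest.mark.parametrize(
        "spec",
        [
            GAMMA,
            LOGISTIC,
            ThermalFunctionSpec(
                "ovip_cubic_exponential", {"a": 1.0, "b": 1.0, "c": 0.5}
            ),
        ],
        ids=["gamma", "logistic", "cubic_exponential"],
    )
    def test_monotone_bounded(self, spec):
        x = np.linspace(0, 20, 2000)
        y = np.asarray(thermal.eval_oviposition_cdf(spec, x))
        assert np.all(np.diff(y) >= -1e-12)
        assert np.all((y >= 0) & (y <= 1))
        assert y[-1] == pytest.approx(1.0, abs=1e-3)


class TestDevtimeCdf:
    def test_median_identity(self):
        b = 4.0
        spec = ThermalFunctionSpec(
            "devtime_logit", {"b": b, "intercepts": [-b * math.log(5.0)]}
        )
        assert thermal.eval_devtime_cdf(spec, 5.0, 0) == pytest.approx(0.5)

    def test_limits(self):
        spec = ThermalFunctionSpec("devtime_logit", {"b": 2.0, "intercepts": [0.0]})
        assert thermal.eval_devtime_cdf(spec, 1e-9, 0) < 1e-6
        assert thermal.eval_devtime_cdf(spec, 1e9, 0) > 1 - 1e-6

    def test_hand_inverted_quantile(self):
        # a=0, b=2: F(x)=0.75 when ln x = logit(0.75)/2 = ln(3)/2
        spec = ThermalFunctionSpec("devtime_logit", {"b": 2.0, "intercepts": [0.0]})
        x = math.exp(math.log(3.0) / 2.0)
        assert thermal.eval_devtime_cdf(spec, x, 0) == pytest.approx(0.75)

    def test_strictly_increasing(self):
        spec = ThermalFunctionSpec("devtime_logit", {"b": 6.0, "intercepts": [-2.0]})
        x = np.linspace(0.1, 40, 500)
        assert np.all(np.diff(thermal.eval_devtime_cdf(spec, x, 0)) > 0)

    def test_nonpositive_time_rejected(self):
        spec = ThermalFunctionSpec("devtime_logit", {"b": 2.0, "intercepts": [0.0]})
        with pytest.raises(ValueError):
            thermal.eval_devtime_cdf(spec, 0.0, 0)


class TestLethalTemperatures:
    def test_never_crossed(self):
        steep = ThermalFunctionSpec(
            "mortality_expquad", {"b1": -11.0, "b2": 0.0, "b3": 0.05}
        )
        lo, hi = thermal.mortality_level_crossings(steep, 0.5)
        assert lo is not None and hi is not None
        # a curve that stays far below the level on the whole search range
        tight = ThermalFunctionSpec(
            "mortality_expquad", {"b1": -50.0, "b2": 0.0, "b3": 0.001}
        )
        lo, hi = thermal.mortality_level_crossings(tight, 0.5)
        assert lo is None and hi is None

    def test_symmetric_spec(self):
        spec = ThermalFunctionSpec(
            "mortality_expquad", {"b1": -5.0, "b2": 0.0, "b3": 0.05}
        )
        lo, hi = thermal.mortality_level_crossings(spec, 0.5)
        assert lo == pytest.approx(-hi, abs=1e-6)

    def test_printed_parameters_level_one(self):
        # quadratic-formula oracle: roots of b1 + b2 T + b3 T^2 = 0
        b1, b2, b3 = 10.271, -0.909, 0.019
        disc = math.sqrt(b2 * b2 - 4 * b3 * b1)
        r_lo, r_hi = (-b2 - disc) / (2 * b3), (-b2 + disc) / (2 * b3)
        lo, hi = thermal.mortality_level_crossings(ROSA_EGG_MORT, 1.0)
        assert lo == pytest.approx(r_lo, abs=1e-4)
        assert hi == pytest.approx(r_hi, abs=1e-4)
        assert lo == pytest.approx(18.30, abs=0.01)
        assert hi == pytest.approx(29.55, abs=0.01)

    def test_roots_consistent_with_mortality(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            spec = ThermalFunctionSpec(
                "mortality_expquad",
                {
                    "b1": rng.uniform(1, 8),
                    "b2": rng.uniform(-1.0, -0.2),
                    "b3": rng.uniform(0.005, 0.03),
                },
            )
            level = rng.uniform(0.1, 0.9)
            lo, hi = thermal.mortality_level_crossings(spec, level)
            for t in (lo, hi):
                if t is not None:
                    assert thermal.eval_mortality(spec, t) == pytest.approx(
                        level, abs=1e-6
                    )

    def test_nesting_invariant(self):
        spec = ThermalFunctionSpec(
            "mortality_expquad", {"b1": -5.0, "b2": 0.0, "b3": 0.05}
        )
        lt = thermal.lethal_temperatures(spec)
        assert lt.lt100_lower <= lt.lt50_lower <= lt.lt50_upper <= lt.lt100_upper

    def test_lt50_absent_when_minimum_mortality_above_half(self):
        # the printed egg curve never drops below ~0.55 mortality, so a 50%
        # crossing does not exist while the 100% boundaries do
        lt = thermal.lethal_temperatures(ROSA_EGG_MORT)
        assert lt.lt50_lower is None and lt.lt50_upper is None
        assert lt.lt100_lower is not None and lt.lt100_upper is not None

    def test_bad_level_rejected(self):
        with pytest.raises(ValueError):
            thermal.mortality_level_crossings(ROSA_EGG_MORT, 0.0)
        with pytest.raises(ValueError):
            thermal.mortality_level_crossings(ROSA_EGG_MORT, 1.5)


class TestLinearLowerThreshold:
    @pytest.mark.parametrize(
        "a,b,expected", [(-0.05, 0.005, 10.0), (0.0, 0.01, 0.0), (-0.048, 0.005, 9.6)]
    )
    def test_values(self, a, b, expected):
        assert thermal.linear_lower_threshold(a, b) == pytest.approx(expected)

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError):
            thermal.linear_lower_threshold(-0.05, 0.0)
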