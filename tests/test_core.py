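"""Exact saturation functions, half-saturation root, local Hill slope."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hillscape import (
    EffectorBinding,
    HillParameters,
    MWCParameters,
    apparent_allosteric_constant,
    half_saturation_concentration,
    hill_fractional_saturation,
    hill_slope_at,
    mwc_fractional_saturation,
    mwc_fractional_saturation_scaled,
)

from conftest import HUMAN_C, HUMAN_K_T, HUMAN_L, naive_mwc_scaled

log_L = st.floats(min_value=-6.0, max_value=8.0)
log_c = st.floats(min_value=-4.0, max_value=-0.01)
log_alpha = st.floats(min_value=-4.0, max_value=4.0)


class TestMWCSaturation:
    @pytest.mark.parametrize(
        "L,c,alpha,expected",
        [
            (0.0, 0.5, 1.0, 0.5),          # pure R: hyperbola half-saturates at a=1
            (1e6, 1.0, 1.0, 0.5),          # c=1 cancels L entirely
            (0.0, 0.01, 3.0, 0.75),        # hyperbola at 3x K
            (1e12, 0.01, 100.0, 0.5),      # pure-T limit half-saturates at c*a=1
        ],
    )
    def test_reference_values(self, L, c, alpha, expected):
        # the T-limit case carries a genuine O(1/(L c^4)) residual
        assert mwc_fractional_saturation_scaled(alpha, L, c) == pytest.approx(
            expected, rel=1e-5
        )

    def test_dimensional_scaled_agreement(self, human_params):
        alpha = np.logspace(-2, 3, 40)
        y_dim = mwc_fractional_saturation(alpha * human_params.K_R, human_params)
        y_sc = mwc_fractional_saturation_scaled(alpha, HUMAN_L, HUMAN_C)
        np.testing.assert_allclose(y_dim, y_sc, rtol=1e-12)

    def test_matches_naive_polynomial_evaluation(self, human_params):
        alpha = np.logspace(-2, 3, 50)
        np.testing.assert_allclose(
            mwc_fractional_saturation_scaled(alpha, HUMAN_L, HUMAN_C),
            naive_mwc_scaled(alpha, HUMAN_L, HUMAN_C),
            rtol=1e-12,
        )

    def test_limits(self, human_params):
        assert mwc_fractional_saturation(0.0, human_params) == 0.0
        assert mwc_fractional_saturation(1e9, human_params) == pytest.approx(1.0)

    def test_stable_at_extreme_L(self):
        p = MWCParameters.from_c(1e12, 1e-6, 143.0)
        S = np.logspace(-4, 6, 200)
        y = mwc_fractional_saturation(S, p)
        assert np.all(np.isfinite(y))
        assert np.all(np.diff(y) > 0)
        assert y[0] < 1e-5 and y[-1] > 0.999

    @settings(derandomize=True, max_examples=60)
    @given(log_L=log_L, log_c=log_c, log_a=log_alpha)
    def test_relabeling_symmetry(self, log_L, log_c, log_a):
        """(L, c, a) and (1/L, 1/c, c*a) describe the same physical model."""
        L, c, a = 10.0**log_L, 10.0**log_c, 10.0**log_a
        y1 = mwc_fractional_saturation_scaled(a, L, c)
        y2 = mwc_fractional_saturation_scaled(c * a, 1.0 / L, 1.0 / c)
        assert y1 == pytest.approx(y2, rel=1e-12, abs=1e-300)

    @settings(derandomize=True, max_examples=60)
    @given(log_L=log_L, log_c=log_c, log_a=log_alpha,
           step=st.floats(min_value=0.01, max_value=1.0))
    def test_strictly_increasing(self, log_L, log_c, log_a, step):
        L, c, a = 10.0**log_L, 10.0**log_c, 10.0**log_a
        assert mwc_fractional_saturation_scaled(
            a * 10.0**step, L, c
        ) > mwc_fractional_saturation_scaled(a, L, c)

    def test_domain_errors(self, human_params):
        with pytest.raises(ValueError):
            mwc_fractional_saturation(-1.0, human_params)
        with pytest.raises(ValueError):
            MWCParameters(L=-1.0, K_R=1.0, K_T=100.0)
        with pytest.raises(ValueError):
            MWCParameters(L=10.0, K_R=0.0, K_T=100.0)
        with pytest.raises(ValueError):
            mwc_fractional_saturation_scaled(1.0, 10.0, c=0.0)


class TestHillSaturation:
    @pytest.mark.parametrize(
        "S,K,nH,expected",
        [
            (50.0, 50.0, 2.74, 0.5),
            (30.0, 10.0, 1.0, 0.75),
            (5.0, 50.0, 4.0, 1e-4 / (1 + 1e-4)),
        ],
    )
    def test_closed_form(self, S, K, nH, expected):
        y = hill_fractional_saturation(S, HillParameters(K, nH))
        assert y == pytest.approx(expected, rel=1e-12)

    def test_monotone_and_bounded(self):
        hp = HillParameters(33.02, 2.74)
        S = np.logspace(-2, 4, 100)
        y = hill_fractional_saturation(S, hp)
        assert np.all(np.diff(y) > 0)
        assert y[0] >= 0 and y[-1] <= 1
        assert hill_fractional_saturation(0.0, hp) == 0.0

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            HillParameters(K_half=-5.0, n_H=2.0)
        with pytest.raises(ValueError):
            HillParameters(K_half=10.0, n_H=5.0)  # exceeds site count


class TestHalfSaturation:
    def test_pure_R_returns_K_R(self):
        hs = half_saturation_concentration(MWCParameters(0.0, 2.5, 250.0))
        assert hs.S_half == pytest.approx(2.5, rel=1e-12)

    def test_c_equal_one_returns_common_K(self):
        hs = half_saturation_concentration(MWCParameters(123.0, 50.0, 50.0))
        assert hs.S_half == pytest.approx(50.0, rel=1e-12)

    def test_pure_T_limit_near_K_T(self):
        p = MWCParameters.from_c(1e12, 0.01, 143.0)
        hs = half_saturation_concentration(p)
        assert hs.S_half == pytest.approx(143.0, rel=5e-3)

    def test_against_grid_bisection_oracle(self, human_params):
        """Dense-grid + bisection on the raw saturation quotient."""
        lo, hi = 1.0, 1.0 / HUMAN_C
        for _ in range(200):  # plain bisection on the independent oracle
            mid = 0.5 * (lo + hi)
            if naive_mwc_scaled(mid, HUMAN_L, HUMAN_C) < 0.5:
                lo = mid
            else:
                hi = mid
        oracle_alpha = 0.5 * (lo + hi)
        hs = half_saturation_concentration(human_params)
        assert hs.alpha_half == pytest.approx(oracle_alpha, rel=1e-10)
        assert hs.S_half == pytest.approx(oracle_alpha * human_params.K_R, rel=1e-10)
        assert mwc_fractional_saturation(hs.S_half, human_params) == pytest.approx(
            0.5, abs=1e-10
        )

    @settings(derandomize=True, max_examples=40)
    @given(log_L=st.floats(min_value=-4, max_value=9), log_c=log_c)
    def test_bracketed_by_state_constants(self, log_L, log_c):
        p = MWCParameters.from_c(10.0**log_L, 10.0**log_c, 143.0)
        hs = half_saturation_concentration(p)
        assert min(p.K_R, p.K_T) <= hs.S_half <= max(p.K_R, p.K_T)
        assert mwc_fractional_saturation(hs.S_half, p) == pytest.approx(0.5, abs=1e-9)


class TestEffectorScaling:
    def test_zero_concentration_returns_base(self):
        eb = EffectorBinding(3300.0, 1.0, 100.0)
        assert apparent_allosteric_constant(eb, 0.0) == 3300.0

    def test_equal_affinities_cancel(self):
        eb = EffectorBinding(3300.0, 5.0, 5.0)
        assert apparent_allosteric_constant(eb, 7.3) == pytest.approx(3300.0)

    def test_closed_form_tetramer(self):
        # K_IR -> infinity: L_app = L (1 + I/K_IT)^4 = 100 * 2^4 at I = K_IT
        eb = EffectorBinding(100.0, 1.0, 1e12)
        assert apparent_allosteric_constant(eb, 1.0) == pytest.approx(1600.0, rel=1e-9)

    def test_inhibitor_strictly_increasing(self):
        eb = EffectorBinding(3300.0, 1.0, 100.0)
        I = np.linspace(0, 20, 50)
        L_app = apparent_allosteric_constant(eb, I)
        assert np.all(np.diff(L_app) > 0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            apparent_allosteric_constant(EffectorBinding(1.0, 1.0, 2.0), -0.1)


class TestHillSlope:
    def test_hyperbola_slope_is_one(self):
        assert hill_slope_at(10.0, MWCParameters(0.0, 2.5, 250.0)) == 1.0
        assert hill_slope_at(10.0, MWCParameters(1e4, 50.0, 50.0)) == 1.0

    def test_human_ridge_point_value(self, human_params):
        """Literature value for the human carrier: n_H = 2.76 at half-saturation."""
        S_half = half_saturation_concentration(human_params).S_half
        assert hill_slope_at(S_half, human_params) == pytest.approx(2.76, abs=0.02)

    def test_agrees_with_finite_difference(self):
        """Analytic slope vs centered difference of the logit, 10x10 grid."""
        h = 1e-6
        worst = 0.0
        for logL in np.linspace(-2, 8, 10):
            for logc in np.linspace(-4, -0.4, 10):
                p = MWCParameters.from_c(10.0**logL, 10.0**logc, 143.0)
                S = half_saturation_concentration(p).S_half
                ana = hill_slope_at(S, p)
                yp = mwc_fractional_saturation(S * math.exp(h), p)
                ym = mwc_fractional_saturation(S * math.exp(-h), p)
                fd = (math.log(yp / (1 - yp)) - math.log(ym / (1 - ym))) / (2 * h)
                worst = max(worst, abs(ana - fd) / abs(fd))
        assert worst <= 1e-6

    @settings(derandomize=True, max_examples=40)
    @given(log_L=st.floats(min_value=-6, max_value=9), log_c=log_c)
    def test_bounded_by_site_count(self, log_L, log_c):
        p = MWCParameters.from_c(10.0**log_L, 10.0**log_c, 143.0)
        S = half_saturation_concentration(p).S_half
        assert 1.0 - 1e-9 <= hill_slope_at(S, p) <= 4.0 + 1e-9

    @pytest.mark.parametrize("L", [1e-8, 1e12])
    def test_limits_in_L(self, L):
        p = MWCParameters.from_c(L, 0.01, 143.0)
        S = half_saturation_concentration(p).S_half
        assert hill_slope_at(S, p) == pytest.approx(1.0, abs=1e-3)

    def test_c_to_one_limit(self):
        p = MWCParameters.from_c(100.0, 0.999999, 143.0)
        S = half_saturation_concentration(p).S_half
        assert hill_slope_at(S, p) == pytest.approx(1.0, abs=1e-4)

    def test_saturated_point_rejected(self, human_params):
        with pytest.raises(ValueError):
            hill_slope_at(1e308, human_params)
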