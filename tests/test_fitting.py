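"""Hill/MWC/global/effector fitters and ordinary least squares."""

import numpy as np
import pytest

from hillscape import (
    EffectorBinding,
    HillParameters,
    MWCParameters,
    SaturationCurve,
    apparent_allosteric_constant,
    fit_effector_binding,
    fit_global_shared_affinities,
    fit_hill,
    fit_mwc,
    half_saturation_concentration,
    hill_fractional_saturation,
    hill_slope_at,
    linear_regression,
    mwc_fractional_saturation,
    sample_curve,
)

from conftest import HUMAN_C, HUMAN_K_T, HUMAN_L

PGRID = np.logspace(0, np.log10(500), 30)


def mwc_curve(L=HUMAN_L, c=HUMAN_C, K_T=HUMAN_K_T, grid=PGRID, label="x"):
    p = MWCParameters.from_c(L, c, K_T)
    return SaturationCurve(grid, mwc_fractional_saturation(grid, p), label=label)


class TestFitHill:
    def test_noiseless_round_trip(self):
        truth = HillParameters(33.02, 2.74)
        S = np.logspace(0, np.log10(300), 20)
        res = fit_hill(SaturationCurve(S, hill_fractional_saturation(S, truth)))
        assert res.converged and res.adequate
        assert res.parameters.K_half == pytest.approx(33.02, rel=1e-6)
        assert res.parameters.n_H == pytest.approx(2.74, rel=1e-6)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_mwc_ridge_curve_recovers_half_saturation_slope(self, human_params):
        """Hill n_H fitted over the 10-90% transition tracks the slope at p50."""
        hs = half_saturation_concentration(human_params)
        nh_true = hill_slope_at(hs.S_half, human_params)
        # pressures spanning 10% to 90% saturation
        from scipy.optimize import brentq

        def y_at(S):
            return mwc_fractional_saturation(S, human_params)

        S10 = brentq(lambda S: y_at(S) - 0.10, 1e-3, 1e4)
        S90 = brentq(lambda S: y_at(S) - 0.90, 1e-3, 1e4)
        S = np.logspace(np.log10(S10), np.log10(S90), 25)
        res = fit_hill(SaturationCurve(S, y_at(S)))
        assert res.converged and res.adequate
        # window-averaged Hill exponent sits a few percent below the
        # half-saturation slope (the MWC logit is not globally linear)
        assert res.parameters.n_H == pytest.approx(nh_true, rel=0.05)
        assert res.parameters.n_H == pytest.approx(2.6363, abs=2e-3)
        assert res.parameters.K_half == pytest.approx(hs.S_half, rel=0.02)

    def test_constant_saturation_flagged_not_raised(self):
        cu = SaturationCurve([1.0, 2.0, 4.0, 8.0, 16.0], [0.5] * 5)
        res = fit_hill(cu)
        assert not res.converged and not res.adequate
        assert res.parameters is None

    def test_pressure_rescaling_moves_p50_not_nh(self):
        truth = HillParameters(33.02, 2.74)
        S = np.logspace(0, np.log10(300), 20)
        y = hill_fractional_saturation(S, truth)
        res1 = fit_hill(SaturationCurve(S, y))
        res2 = fit_hill(SaturationCurve(S * 7.5, y))
        assert res2.parameters.n_H == pytest.approx(res1.parameters.n_H, rel=1e-8)
        assert res2.parameters.K_half == pytest.approx(
            7.5 * res1.parameters.K_half, rel=1e-8
        )

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_hill(SaturationCurve([1.0, 2.0, 4.0], [0.1, 0.4, 0.8]))


class TestFitMWC:
    def test_noiseless_round_trip(self):
        res = fit_mwc(mwc_curve())
        assert res.converged and res.adequate
        p = res.parameters
        assert p.L == pytest.approx(HUMAN_L, rel=1e-4)
        assert p.K_T == pytest.approx(HUMAN_K_T, rel=1e-4)
        assert p.c == pytest.approx(HUMAN_C, rel=1e-4)

    def test_fixing_L_recovers_affinities_exactly(self):
        res = fit_mwc(mwc_curve(), fixed={"L": HUMAN_L})
        assert res.parameters.K_R == pytest.approx(HUMAN_C * HUMAN_K_T, rel=1e-6)
        assert res.parameters.K_T == pytest.approx(HUMAN_K_T, rel=1e-6)

    def test_noisy_identifiability_envelope(self):
        """Median |error in log10 L| stays below 0.3 at 1% saturation noise."""
        truth = MWCParameters.from_c(HUMAN_L, HUMAN_C, HUMAN_K_T)
        errs = []
        for rep in range(12):
            cu = sample_curve(truth, PGRID, noise_sd=0.01, seed=100 + rep)
            res = fit_mwc(cu)
            errs.append(abs(np.log10(res.parameters.L) - np.log10(HUMAN_L)))
        assert np.median(errs) < 0.3

    def test_unknown_fixed_name_rejected(self):
        with pytest.raises(ValueError):
            fit_mwc(mwc_curve(), fixed={"bogus": 1.0})


class TestGlobalFit:
    def test_noiseless_panel_recovers_all_L_app(self):
        L_apps = [10**3, 10**3.5, 10**4, 10**4.5, 10**5]
        curves = [mwc_curve(L=L, label=f"c{i}") for i, L in enumerate(L_apps)]
        res = fit_global_shared_affinities(curves)
        assert res.converged
        np.testing.assert_allclose(res.L_app, L_apps, rtol=1e-3)
        assert res.c == pytest.approx(HUMAN_C, rel=1e-4)

    def test_single_curve_matches_per_curve_fit(self):
        cu = mwc_curve()
        g = fit_global_shared_affinities([cu])
        s = fit_mwc(cu)
        assert g.L_app[0] == pytest.approx(s.parameters.L, rel=1e-6)
        assert g.K_R == pytest.approx(s.parameters.K_R, rel=1e-6)
        assert g.r_squared == pytest.approx(s.r_squared, abs=1e-12)

    def test_noisy_panel_preserves_L_ordering(self):
        L_apps = [10**3, 10**3.5, 10**4, 10**4.5, 10**5]
        truth = [MWCParameters.from_c(L, HUMAN_C, HUMAN_K_T) for L in L_apps]
        curves = [
            sample_curve(t, PGRID, noise_sd=0.01, seed=5, _index=i, label=f"c{i}")
            for i, t in enumerate(truth)
        ]
        res = fit_global_shared_affinities(curves)
        assert np.all(np.diff(np.log10(res.L_app)) > 0)


class TestFitEffector:
    I_GRID = np.array([0.0, 0.5, 1.0, 2.0, 5.0, 10.0])

    def test_exact_recovery(self):
        eb = EffectorBinding(3300.0, 1.0, 100.0)
        L_app = apparent_allosteric_constant(eb, self.I_GRID)
        res = fit_effector_binding(self.I_GRID, L_app)
        assert res.converged
        assert res.parameters.L_base == pytest.approx(3300.0, rel=1e-6)
        assert res.parameters.K_IT == pytest.approx(1.0, rel=1e-6)
        assert res.parameters.K_IR == pytest.approx(100.0, rel=1e-6)

    def test_zero_concentration_only_flags_affinities(self):
        res = fit_effector_binding([0.0] * 5, [3300.0] * 5)
        assert res.parameters.L_base == pytest.approx(3300.0, rel=1e-6)
        flagged = res.unidentifiable
        assert "log10_K_IT" in flagged and "log10_K_IR" in flagged

    def test_noisy_replicates_recover_L_base(self):
        eb = EffectorBinding(3300.0, 1.0, 100.0)
        L_app = apparent_allosteric_constant(eb, self.I_GRID)
        estimates = []
        for rep in range(15):
            rng = np.random.default_rng(rep)
            noisy = 10 ** (np.log10(L_app) + rng.normal(0, 0.05, L_app.size))
            res = fit_effector_binding(self.I_GRID, noisy)
            estimates.append(res.parameters.L_base)
        assert abs(np.median(estimates) / 3300.0 - 1.0) < 0.10

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            fit_effector_binding([0.0, 1.0, 2.0], [10.0, 20.0, 30.0])


class TestLinearRegression:
    def test_exact_line(self):
        x = np.linspace(-3, 0, 10)
        res = linear_regression(x, -2.0 * x)
        assert res.slope == pytest.approx(-2.0, abs=1e-12)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_zero_x_variance_rejected(self):
        with pytest.raises(ValueError):
            linear_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            linear_regression([1.0, 2.0], [1.0, 2.0])
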