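import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp

from denikin import scenarios, synthetic_data
from denikin.fitting import (
    CapacityOLS,
    InhibitionModel,
    LogisticGrowthModel,
    calibrate_initial_biomass,
    compare_scenarios,
    extract_growth_rates,
    fit_capacity_ols,
    fit_conversion,
    fit_inhibition,
    fit_logistic,
    fit_monod,
    logistic_curve,
    validate_growth_table,
)
from denikin.simulation import integrate


class TestLogisticFit:
    def test_exact_recovery_on_noiseless_data(self):
        t = np.arange(0, 100, 1.0)
        od = logistic_curve(t, 0.1, 0.5, 0.01)
        res = fit_logistic(t, od)
        assert res.estimate("mu_max") == pytest.approx(0.1, rel=1e-6)
        assert res.estimate("X_m") == pytest.approx(0.5, rel=1e-6)
        assert res.estimate("X0") == pytest.approx(0.01, rel=1e-6)
        assert res.converged

    def test_flat_series_flagged_unconverged(self):
        t = np.arange(0, 10, 0.5)
        res = fit_logistic(t, np.full_like(t, 0.05))
        assert not res.converged

    def test_mean_recovery_under_multiplicative_noise(self):
        rng = np.random.default_rng(42)
        t = np.linspace(0, 100, 50)
        truth = logistic_curve(t, 0.1, 0.5, 0.01)
        mus = []
        for _ in range(20):
            od = truth * np.exp(rng.normal(0, 0.05, t.size))
            mus.append(fit_logistic(t, od).estimate("mu_max"))
        assert np.mean(mus) == pytest.approx(0.1, rel=0.02)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic([0, 1, 2], [0.1, 0.2, 0.3])

    def test_estimator_api(self):
        t = np.arange(0, 80, 1.0)
        est = LogisticGrowthModel().fit(t, logistic_curve(t, 0.15, 0.4, 0.02))
        assert est.get_params()["n_starts"] == 5
        pred = est.predict(t)
        assert np.allclose(pred, logistic_curve(t, 0.15, 0.4, 0.02), rtol=1e-5)


class TestMonodFit:
    def test_exact_recovery(self):
        S = np.array([0.5, 1, 2, 4, 8, 16])
        res = fit_monod(S, 0.2 * S / (S + 2))
        assert res.estimate("mu_max") == pytest.approx(0.2, rel=1e-6)
        assert res.estimate("K_s") == pytest.approx(2.0, rel=1e-6)

    def test_dose_independent_rate_gives_zero_ks(self):
        S = np.array([2, 5, 10, 20, 30], dtype=float)
        res = fit_monod(S, np.full(5, 0.1))
        assert res.estimate("K_s") == pytest.approx(0.0, abs=1e-8)

    def test_linear_regime_flagged_poorly_identified(self):
        S = np.array([0.1, 0.2, 0.4, 0.8, 1.6])
        res = fit_monod(S, 0.001 * S)  # far below saturation
        assert res.estimate("K_s") > S.max()
        assert "poorly_identified" in res.flags

    def test_needs_three_distinct_levels(self):
        with pytest.raises(ValueError):
            fit_monod([1, 1, 1, 1], [0.1, 0.1, 0.1, 0.1])

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(3)
        S = np.repeat([0.5, 1, 2, 4, 8], 4)
        mu = 0.2 * S / (S + 2) * np.exp(rng.normal(0, 0.02, S.size))
        res1 = fit_monod(S, mu)
        perm = rng.permutation(S.size)
        res2 = fit_monod(S[perm], mu[perm])
        assert res1.estimate("K_s") == pytest.approx(res2.estimate("K_s"), rel=1e-8)


class TestInhibitionFit:
    def test_recovers_self_inhibiting_nitrite_reducer_constant(self):
        # substrate is also the inhibitor (nitrite reducer)
        rng = np.random.default_rng(7)
        I = np.repeat([1, 2, 4, 6, 8, 10, 14, 20], 8).astype(float)
        mu = 0.16 * I / (I + 0.5) / (1 + I / 13.23)
        mu = mu * np.exp(rng.normal(0, 0.01, I.size))
        res = fit_inhibition(I, mu, base={"mu_max": 0.16, "K_s": 0.5}, substrate="inhibitor")
        assert res.estimate("K_i") == pytest.approx(13.23, rel=0.05)

    def test_recovers_constant_with_fixed_substrate(self):
        rng = np.random.default_rng(8)
        I = np.repeat([0, 1, 2, 4, 6, 8, 10], 8).astype(float)
        mu = 0.25 * 10 / 10.05 / (1 + I / 9.11)
        mu = mu * np.exp(rng.normal(0, 0.01, I.size))
        res = fit_inhibition(I, mu, base={"mu_max": 0.25, "K_s": 0.05}, substrate=10.0)
        assert res.estimate("K_i") == pytest.approx(9.11, rel=0.05)

    def test_no_decline_reports_infinite_ki(self):
        I = np.array([0, 1, 2, 4, 8], dtype=float)
        mu = np.array([0.05, 0.08, 0.1, 0.11, 0.12])
        res = fit_inhibition(I, mu, base={"mu_max": 0.12, "K_s": 1.0}, substrate=10.0)
        assert math.isinf(res.estimate("K_i"))
        assert "no_inhibition" in res.flags

    def test_joint_fit_without_base(self):
        I = np.array([0.5, 1, 2, 4, 6, 8, 10, 14, 20])
        mu = 0.16 * I / (I + 0.5) / (1 + I / 13.23)
        est = InhibitionModel(substrate="inhibitor").fit(I, mu)
        assert est.k_i_ == pytest.approx(13.23, rel=0.02)
        assert est.mu_max_ == pytest.approx(0.16, rel=0.02)

    def test_requires_four_levels(self):
        with pytest.raises(ValueError):
            fit_inhibition([1, 2, 3], [0.1, 0.09, 0.08], base={"mu_max": 0.1, "K_s": 1})

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(5)
        I = np.repeat([1, 2, 5, 10, 20], 3).astype(float)
        mu = 0.2 * I / (I + 1) / (1 + I / 8) * np.exp(rng.normal(0, 0.01, I.size))
        r1 = fit_inhibition(I, mu, base={"mu_max": 0.2, "K_s": 1.0}, substrate="inhibitor")
        perm = rng.permutation(I.size)
        r2 = fit_inhibition(I[perm], mu[perm], base={"mu_max": 0.2, "K_s": 1.0},
                            substrate="inhibitor")
        assert r1.estimate("K_i") == pytest.approx(r2.estimate("K_i"), rel=1e-8)


class TestCapacityOLS:
    def test_exact_nitrate_slope(self):
        no3 = np.array([1, 2, 4, 6, 8, 10], dtype=float)
        res = fit_capacity_ols(pd.DataFrame({"NO3": no3}), 0.033 * no3)
        assert res.estimate("NO3") == pytest.approx(0.033, rel=1e-10)

    def test_exact_nitrite_slope(self):
        no2 = np.array([1, 2, 4, 6, 8, 10], dtype=float)
        res = fit_capacity_ols(pd.DataFrame({"NO2": no2}), 0.032 * no2)
        assert res.estimate("NO2") == pytest.approx(0.032, rel=1e-10)

    def test_two_substrate_design(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"NO3": rng.uniform(1, 10, 12), "NO2": rng.uniform(0, 10, 12)})
        y = 0.033 * X["NO3"] + 0.032 * X["NO2"]
        res = fit_capacity_ols(X, y)
        assert res.estimate("NO3") == pytest.approx(0.033, rel=1e-8)
        assert res.estimate("NO2") == pytest.approx(0.032, rel=1e-8)

    def test_zero_response_gives_zero_betas(self):
        X = pd.DataFrame({"NO3": [1.0, 2, 4, 8]})
        res = fit_capacity_ols(X, np.zeros(4))
        assert res.estimate("NO3") == 0.0

    def test_collinear_columns_named(self):
        no3 = np.array([1, 2, 4, 8.0])
        X = pd.DataFrame({"NO3": no3, "NO3_dup": 2 * no3})
        with pytest.raises(ValueError, match="NO3"):
            fit_capacity_ols(X, 0.033 * no3)

    def test_predict(self):
        no3 = np.array([1, 2, 4, 6, 8, 10], dtype=float)
        est = CapacityOLS().fit(pd.DataFrame({"NO3": no3}), 0.033 * no3)
        assert est.predict(pd.DataFrame({"NO3": [20.0]}))[0] == pytest.approx(0.66)


class TestConversionFit:
    @staticmethod
    def _depletion(vmax, km, t, X, s0):
        def rhs(ti, y):
            s = max(y[0], 0.0)
            return [-vmax * s / (s + km) * np.interp(ti, t, X)]

        sol = solve_ivp(rhs, (t[0], t[-1]), [s0], t_eval=t, rtol=1e-10, atol=1e-12)
        return sol.y[0]

    def test_parameter_recovery(self):
        t = np.arange(0, 72, 0.25)
        X = logistic_curve(t, 0.12, 0.3, 0.01)
        S = self._depletion(2.0, 1.0, t, X, 10.0)
        res = fit_conversion(t, S, X)
        assert res.estimate("V_max") == pytest.approx(2.0, rel=0.05)
        assert res.estimate("K_m") == pytest.approx(1.0, rel=0.05)

    def test_constant_substrate_gives_zero_vmax(self):
        t = np.arange(0, 24, 0.5)
        res = fit_conversion(t, np.full_like(t, 5.0), logistic_curve(t, 0.1, 0.3, 0.01))
        assert res.estimate("V_max") == pytest.approx(0.0, abs=1e-6)

    def test_decline_without_biomass_rejected(self):
        t = np.arange(0, 24, 0.5)
        S = np.linspace(10, 2, t.size)
        with pytest.raises(ValueError, match="unexplained"):
            fit_conversion(t, S, np.zeros_like(t))

    def test_increasing_substrate_rejected(self):
        t = np.arange(0, 24, 0.5)
        with pytest.raises(ValueError, match="increases"):
            fit_conversion(t, np.linspace(2, 10, t.size), np.full_like(t, 0.1))


class TestCalibrateInitialBiomass:
    def test_recovers_true_inoculum(self, default_params):
        model = scenarios.build("mono_3H11", params=default_params)
        truth = scenarios.initial_state("mono_3H11", params=default_params, inoculum_od=0.001)
        observed = integrate(model, truth, t_end=100, t_step=0.5)
        cal = calibrate_initial_biomass(model, observed, inoculum_od=0.01)
        assert cal.x0["3H11"] == pytest.approx(0.001, rel=0.02)
        assert cal.rmse <= cal.rmse_initial

    def test_recovers_upper_bound(self, default_params):
        model = scenarios.build("mono_3H11", params=default_params)
        truth = scenarios.initial_state("mono_3H11", params=default_params, inoculum_od=0.01)
        observed = integrate(model, truth, t_end=100, t_step=0.5)
        cal = calibrate_initial_biomass(model, observed, inoculum_od=0.01)
        assert cal.x0["3H11"] == pytest.approx(0.01, rel=0.02)

    def test_flat_observation_returns_lower_bound(self, default_params):
        model = scenarios.build("mono_3H11", params=default_params)
        t = np.arange(0, 50, 0.5)
        flat = np.full_like(t, 0.01)
        from denikin.simulation import TimeCourse

        observed = TimeCourse(
            t=t, X={"3H11": flat}, S={"NO3": np.full_like(t, 10.0)}
        )
        cal = calibrate_initial_biomass(model, observed, inoculum_od=0.01)
        assert "flat_observation" in cal.flags
        assert cal.x0["3H11"] == pytest.approx(1e-6)


class TestCompareScenarios:
    def test_generating_scenario_scores_best(self, default_params):
        mA = scenarios.build("syncom_A", params=default_params)
        mB = scenarios.build("syncom_B", params=default_params)
        init = scenarios.initial_state("syncom_B", params=default_params)
        data = integrate(mB, init, t_end=150, t_step=1.0)
        table = compare_scenarios({"A": mA, "B": mB}, data, init)
        totals = table[table.variable == "total"].set_index("scenario")["rmse"]
        assert totals["B"] < totals["A"]
        assert totals["B"] == pytest.approx(0.0, abs=1e-8)

    def test_identical_models_tie(self, default_params):
        mA = scenarios.build("syncom_A", params=default_params)
        init = scenarios.initial_state("syncom_A", params=default_params)
        data = integrate(mA, init, t_end=100, t_step=1.0)
        table = compare_scenarios({"first": mA, "second": mA}, data, init)
        totals = table[table.variable == "total"].set_index("scenario")["rmse"]
        assert totals["first"] == pytest.approx(totals["second"])

    def test_no_overlap_rejected(self, default_params):
        from denikin.simulation import TimeCourse

        mA = scenarios.build("syncom_A", params=default_params)
        init = scenarios.initial_state("syncom_A", params=default_params)
        t = np.arange(0, 10, 1.0)
        data = TimeCourse(t=t, X={"unknown_species": np.ones_like(t)}, S={})
        data.S.clear()  # no shared pools either
        with pytest.raises(ValueError):
            compare_scenarios({"A": mA}, data, init)


class TestGrowthRateExtraction:
    def test_window_recovers_initial_rates(self):
        noise = synthetic_data.NoiseSpec(od_sd=0.0, conc_sd_mM=0.0, seed=1)
        growth, _, _ = synthetic_data.generate_monoculture_titration(
            "R12", "NO2", [2, 4, 8], reps=1, noise=noise
        )
        rates = extract_growth_rates(growth, "no2_mM").set_index("no2_mM")["mu_max"]
        for level in (2, 4, 8):
            expected = 0.16 * level / (level + 0.5) / (1 + level / 13.23)
            assert rates[level] == pytest.approx(expected, rel=0.02)

    def test_flat_level_marked_unconverged(self):
        noise = synthetic_data.NoiseSpec(od_sd=0.0, conc_sd_mM=0.0, seed=1)
        growth, _, _ = synthetic_data.generate_monoculture_titration(
            "R12", "NO2", [0, 4], reps=1, noise=noise
        )
        rates = extract_growth_rates(growth, "no2_mM")
        zero_row = rates[rates["no2_mM"] == 0].iloc[0]
        assert not zero_row["converged"]
        assert zero_row["mu_max"] == 0.0

    def test_schema_validation(self):
        with pytest.raises(ValueError, match="missing columns"):
            validate_growth_table(pd.DataFrame({"time_h": [0.0]}))


class TestEndToEndRecovery:
    """Full pipeline on generated titrations recovers the generating parameters."""

    def test_nitrite_reducer_joint_kinetics_recovery(self):
        # titration reaches below K_s (0.5 mM) so saturation is identifiable;
        # the smaller inoculum keeps capacity above inoculum at the low levels
        noise = synthetic_data.NoiseSpec(od_sd=0.05, conc_sd_mM=0.0, seed=11)
        growth, _, _ = synthetic_data.generate_monoculture_titration(
            "R12", "NO2", [0.5, 1, 2, 4, 6, 8, 10, 14, 20], reps=8, noise=noise,
            inoculum_od=0.002,
        )
        rates = extract_growth_rates(growth, "no2_mM", od_window=0.5)
        ok = rates[rates.converged]
        est = InhibitionModel(substrate="inhibitor").fit(
            ok["no2_mM"].to_numpy(), ok["mu_max"].to_numpy()
        )
        assert est.mu_max_ == pytest.approx(0.16, rel=0.10)
        assert est.k_s_ == pytest.approx(0.5, rel=0.10)
        assert est.k_i_ == pytest.approx(13.23, rel=0.10)

    def test_capacity_slopes_recovery_under_noise(self):
        noise = synthetic_data.NoiseSpec(od_sd=0.05, conc_sd_mM=0.0, seed=12)
        growth, _, _ = synthetic_data.generate_monoculture_titration(
            "R12", "NO3", [1, 2, 4, 6, 8, 10], reps=8, noise=noise, t_end=300
        )
        # plateau estimate: average OD over the final stretch of each curve
        # (unbiased under multiplicative noise, unlike the noisy maximum)
        tail = growth[growth.time_h >= 270]
        plateau = (
            tail.groupby(["no3_mM", "replicate"])["od600"].mean().reset_index()
        )
        res = fit_capacity_ols(plateau[["no3_mM"]], plateau["od600"])
        assert res.estimate("no3_mM") == pytest.approx(0.033, rel=0.10)

    def test_fast_reducer_n2o_rate_is_dose_independent(self):
        pts = synthetic_data.generate_rate_dose_response(
            "3H11", "N2O", [2, 5, 10, 20, 30], reps=8, rel_sd=0.05, seed=13
        )
        res = fit_monod(pts["level_mM"], pts["mu"])
        assert res.estimate("K_s") == pytest.approx(0.0, abs=0.1)
        assert res.estimate("mu_max") == pytest.approx(0.10, rel=0.10)

    @pytest.mark.parametrize("noise_sd", [0.0, 0.02, 0.05])
    def test_monod_bias_vanishes_with_noise(self, noise_sd):
        rng = np.random.default_rng(17)
        S = np.repeat([0.25, 0.5, 1, 2, 4, 8, 16], 8).astype(float)
        mu = 0.2 * S / (S + 2)
        obs = mu * np.exp(rng.normal(0, noise_sd, S.size)) if noise_sd else mu
        res = fit_monod(S, obs)
        tol = max(5 * noise_sd, 1e-6)
        assert res.estimate("K_s") == pytest.approx(2.0, rel=tol)
        assert res.estimate("mu_max") == pytest.approx(0.2, rel=tol)


class TestFitResultContract:
    def test_invariants_enforced(self):
        from denikin.fitting import FitResult

        with pytest.raises(ValueError):
            FitResult(
                parameters={"a": (1.0, -0.1)},
                r_squared=0.5,
                residuals=np.zeros(3),
                n_points=3,
                converged=True,
                method="m",
            )
        with pytest.raises(ValueError):
            FitResult(
                parameters={},
                r_squared=0.5,
                residuals=np.zeros(2),
                n_points=3,
                converged=True,
                method="m",
            )
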