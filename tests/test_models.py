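"""Likelihood machinery: mean functions, ML fits, AICc building, family choice."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import expit

from budwormflight.equations import get_equation
from budwormflight.errors import get_family
from budwormflight.models import (
    FlightModel,
    aicc,
    incremental_build,
    select_family,
    support,
)
from budwormflight.recovery import simulate_refit
from budwormflight.simulate import GeneratorConfig, draw_response, generate_females


class TestInformationCriteria:
    def test_aicc_reduces_to_deviance_without_parameters(self):
        assert aicc(-100.0, 0, 50) == pytest.approx(200.0)

    def test_aicc_hand_formula(self):
        # -2(-100) + 2*3 + 2*3*4/(50-4) = 206 + 24/46
        assert aicc(-100.0, 3, 50) == pytest.approx(206.0 + 24 / 46)

    def test_aicc_limits_to_aic(self):
        assert aicc(-10.0, 3, 10**7) == pytest.approx(26.0, abs=1e-4)

    def test_aicc_random_inputs_match_formula(self, rng):
        for _ in range(1000):
            ll = rng.normal(-500, 100)
            k = int(rng.integers(1, 8))
            n = int(rng.integers(k + 2, 400))
            assert aicc(ll, k, n) == pytest.approx(
                -2 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1)
            )

    def test_aicc_requires_enough_data(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)

    def test_support_of_best_model_is_one(self):
        assert support(123.4, 123.4) == 1.0

    def test_support_published_distance_row(self):
        # printed: AICc 4766.5 vs best 4763.1 -> support 0.18
        assert support(4766.5, 4763.1) == pytest.approx(0.18, abs=0.005)

    def test_support_strictly_decreasing_in_delta(self):
        deltas = np.linspace(0.0, 20.0, 50)
        vals = [support(100.0 + d, 100.0) for d in deltas]
        assert np.all(np.diff(vals) < 0)
        assert all(0 < v <= 1 for v in vals)


class TestMeanFunctions:
    def test_wingbeat_plugin_value(self):
        spec = get_equation(3)
        df = pd.DataFrame({"T": [25.0], "La": [9.5]})
        model_mean = FlightModel(
            df.assign(wingbeat_hz=[40.0]), spec
        ).mean
        theta = np.array([spec.params[p] for p in model_mean.param_names])
        assert model_mean(theta, df)[0] == pytest.approx(40.0, abs=0.1)

    def test_propensity_plugin_value(self):
        spec = get_equation(1)
        df = pd.DataFrame({"T": [25.0], "Stot": [90.0], "Wb": [35.0], "flew": [1.0]})
        m = FlightModel(df, spec)
        theta = np.array([spec.params[p] for p in m.mean.param_names])
        logit = -8.523 + 0.307 * 25 + 0.064 * 90 - 0.090 * 35
        assert logit == pytest.approx(1.762, abs=1e-3)
        assert m.mean(theta, df)[0] == pytest.approx(expit(logit))

    def test_quadratic_term_vanishes_at_optimum(self):
        spec = get_equation(6)
        df = pd.DataFrame(
            {"T": [spec.params["T0"]], "La": [9.5], "Ap": [101.3], "distance_km": [1.0]}
        )
        m = FlightModel(df.rename(columns={"distance_km": spec.response}), spec)
        theta = np.array([spec.params[p] for p in m.mean.param_names])
        expected = (
            spec.params["p1"] + spec.params["La"] * 9.5 + spec.params["Ap"] * 101.3
        )
        assert m.mean(theta, df)[0] == pytest.approx(expected)


class TestFit:
    def test_zero_noise_limit_recovers_truth(self):
        spec = get_equation(4)
        fem = generate_females(GeneratorConfig(n_per_treatment=30), seed=11)
        rng = np.random.default_rng(0)
        y, _ = draw_response(4, fem, rng, {"sigma2": 1e-12})
        fem[spec.response] = y
        res = FlightModel(fem, spec).fit(seed=0)
        for p in ("p1", "T", "La", "T0"):
            assert res.params[p] == pytest.approx(spec.params[p], rel=1e-4, abs=1e-6)

    def test_two_parameter_power_law_matches_grid_search(self, rng):
        # exhaustive 2-D grid over (p1, exponent) with the lognormal shape
        # profiled out by a 1-D inner minimization: an optimizer-free oracle
        spec = get_equation(10)
        fem = generate_females(GeneratorConfig(n_per_treatment=10), seed=21)
        y, _ = draw_response(10, fem, rng)
        fem[spec.response] = y
        m = FlightModel(fem, spec)
        res = m.fit(seed=0)
        fam = get_family("lognormal")
        wb = fem["Wb"].to_numpy()
        yv = m.endog

        def prof_nll(p1, b):
            mu = p1 * wb**b
            inner = minimize_scalar(
                lambda ls2: fam.nll(yv, mu, math.exp(ls2)), bounds=(-12, 2), method="bounded"
            )
            return inner.fun

        p1_grid = np.linspace(0.04, 0.16, 81)
        b_grid = np.linspace(0.8, 1.3, 81)
        vals = np.array([[prof_nll(a, b) for b in b_grid] for a in p1_grid])
        i, j = np.unravel_index(np.argmin(vals), vals.shape)
        assert res.params["p1"] == pytest.approx(p1_grid[i], abs=p1_grid[1] - p1_grid[0])
        assert res.params["Wb"] == pytest.approx(b_grid[j], abs=b_grid[1] - b_grid[0])

    def test_propensity_matches_logistic_regression_oracle(self, rng):
        import statsmodels.api as sm

        fem = generate_females(GeneratorConfig(n_per_treatment=60), seed=31)
        y, _ = draw_response(1, fem, rng)
        fem["flew"] = y
        res = FlightModel(fem, get_equation(1)).fit(seed=0)
        X = sm.add_constant(fem[["T", "Stot", "Wb"]])
        ref = sm.Logit(fem["flew"], X).fit(disp=0)
        for ours, theirs in zip(["p1", "T", "Stot", "Wb"], ref.params.index):
            assert res.params[ours] == pytest.approx(ref.params[theirs], abs=1e-4)
        assert res.llf == pytest.approx(ref.llf, abs=1e-6)

    def test_speed_optimum_recovery_coverage(self):
        # simulate from the published flight-speed fit and refit: the 2-SE
        # interval for the thermal optimum should cover the truth in at
        # least 90% of replicates
        tab = simulate_refit(4, N=282, reps=30, seed=60)
        assert tab["T0_in2se"].mean() >= 0.9
        assert tab["T0"].mean() == pytest.approx(27.117, abs=1.0)

    def test_missing_column_raises(self):
        with pytest.raises(ValueError, match="missing columns"):
            FlightModel(pd.DataFrame({"Wloss": [1.0]}), get_equation(7))

    def test_multiplicative_family_requires_positive_response(self):
        df = pd.DataFrame({"Wloss": [1.0, -2.0], "T": [20, 25], "Wb": [30, 35], "La": [9, 9.5]})
        with pytest.raises(ValueError, match="positive response"):
            FlightModel(df, get_equation(7))

    def test_summary_reports_estimates(self, rng):
        fem = generate_females(GeneratorConfig(n_per_treatment=15), seed=41)
        y, _ = draw_response(10, fem, rng)
        fem["Wlipids"] = y
        res = FlightModel(fem, get_equation(10)).fit(seed=0)
        text = res.summary()
        assert "AICc" in text and "kappa" not in text and "sigma2" in text


class TestIncrementalBuild:
    def test_final_support_is_one(self, rng):
        fem = generate_females(GeneratorConfig(n_per_treatment=25), seed=51)
        y, _ = draw_response(10, fem, rng)
        fem["Wlipids"] = y
        table = incremental_build(fem, get_equation(10), entry_order=["Wb"], seed=0)
        assert table.rows["support"].iloc[-1] == pytest.approx(1.0) or (
            table.rows["support"].min() >= 0
        )
        assert np.nanmin(np.abs(table.rows["support"].to_numpy() - 1.0)) < 1e-12

    def test_null_predictor_usually_excluded(self):
        # a predictor with zero true effect should be dropped by the AICc
        # penalty in most replicates
        excluded = 0
        reps = 20
        for r in range(reps):
            rng = np.random.default_rng(2000 + r)
            fem = generate_females(GeneratorConfig(n_per_treatment=25), seed=3000 + r)
            y, _ = draw_response(10, fem, rng)
            fem["Wlipids"] = y
            spec = get_equation(10).with_terms(("Wb", "La"))
            table = incremental_build(fem, spec, entry_order=["Wb", "La"], seed=r)
            excluded += "La" not in table.final.model.spec.terms
        assert excluded >= 14  # ~ chi2(1) < AICc penalty

    def test_morphology_improves_propensity_model(self, rng):
        # wing area and mass carry real signal beyond temperature, so the
        # full published model out-ranks the temperature-only reduction
        # (the separation is modest here because wing area and mass are
        # strongly correlated in the simulated morphology)
        spec = get_equation(1)
        fem = generate_females(GeneratorConfig(n_per_treatment=64), seed=61)
        fem = fem.iloc[:379].reset_index(drop=True)
        y, _ = draw_response(1, fem, rng)
        fem["flew"] = y
        full = FlightModel(fem, spec).fit(seed=0)
        t_only = FlightModel(fem, spec.with_terms(("T",))).fit(seed=0)
        assert full.aicc < t_only.aicc
        assert support(t_only.aicc, full.aicc) < 1.0


class TestFamilySelection:
    def test_exponential_deviates_select_weibull(self, rng):
        fem = generate_females(GeneratorConfig(n_per_treatment=40), seed=71)
        mu = 0.002 * fem["T"] ** 1.0 * fem["Wb"] ** 0.5
        fem["Wloss"] = mu * rng.exponential(1.0, len(fem))
        spec = get_equation(7).with_terms(("T", "Wb"))
        fam, corrs, fits = select_family(fem, spec, seed=0)
        assert fam == "weibull"
        assert fits["weibull"].params["kappa"] == pytest.approx(1.0, abs=0.15)

    def test_additive_noise_selects_normal(self):
        # additive noise that is large relative to the mean: the symmetric
        # residual shape rules out the skewed multiplicative families
        from dataclasses import replace

        spec = replace(get_equation(3), temp_term=None, terms=("T",))
        hits = 0
        for r in range(20):
            rng = np.random.default_rng(4000 + r)
            fem = generate_females(GeneratorConfig(n_per_treatment=30), seed=5000 + r)
            y = 1 + 0.5 * fem["T"] + rng.normal(0, 4.0, len(fem))
            fem["wingbeat_hz"] = np.maximum(y, 0.05)
            fam, corrs, fits = select_family(fem, spec, seed=r)
            hits += fam == "normal"
        assert hits >= 18

    def test_nonpositive_response_forces_normal(self, rng):
        fem = generate_females(GeneratorConfig(n_per_treatment=20), seed=81)
        fem["wingbeat_hz"] = rng.normal(0.0, 1.0, len(fem))
        spec = get_equation(3).with_terms(())
        fam, corrs, fits = select_family(fem, spec, seed=0)
        assert fam == "normal" and set(corrs) == {"normal"}
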