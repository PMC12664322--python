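"""Monte-Carlo confidence bands, deviation displays, temperature curves."""

import numpy as np
import pandas as pd
import pytest

from budwormflight.equations import get_equation
from budwormflight.models import FlightModel, FlightResults
from budwormflight.recovery import simulate_refit
from budwormflight.simulate import GeneratorConfig, draw_response, generate_females
from budwormflight.uncertainty import deviation_series, mc_confidence_band, mean_curve


@pytest.fixture(scope="module")
def lipid_fit():
    rng = np.random.default_rng(17)
    fem = generate_females(GeneratorConfig(n_per_treatment=25), seed=17)
    y, _ = draw_response(10, fem, rng)
    fem["Wlipids"] = y
    model = FlightModel(fem, get_equation(10))
    return model.fit(seed=0)


class TestConfidenceBand:
    def test_zero_se_band_collapses_to_mean_curve(self, lipid_fit):
        res = FlightResults(
            model=lipid_fit.model,
            params=lipid_fit.params,
            bse=lipid_fit.bse * 0.0,
            llf=lipid_fit.llf,
            converged=True,
            hess_pd=True,
        )
        grid = pd.DataFrame({"Wb": np.linspace(25, 50, 11)})
        band = mc_confidence_band(res, grid, reps=200, seed=0)
        assert np.allclose(band["lower"], band["mean"], atol=1e-12)
        assert np.allclose(band["upper"], band["mean"], atol=1e-12)

    def test_acceptance_fraction_monotone_in_alpha(self, lipid_fit):
        grid = pd.DataFrame({"Wb": np.linspace(25, 50, 5)})
        fracs = []
        for alpha in (0.2, 0.05, 0.01):
            band = mc_confidence_band(
                lipid_fit, grid, alpha=alpha, reps=2000, max_reps=2000,
                target_accept=10**9, seed=1,
            )
            fracs.append(band.attrs["n_accepted"] / band.attrs["n_draws"])
        assert fracs[0] < fracs[1] < fracs[2]

    def test_linear_toy_band_matches_profile_likelihood(self, rng):
        # one-parameter model y = m + eps: the envelope of accepted draws at
        # the data mean should approximate the profile-likelihood interval
        n = 80
        y = rng.normal(5.0, 1.0, n)
        df = pd.DataFrame({"y": y})
        from budwormflight.equations import ModelSpec

        spec = ModelSpec(eq_id=0, response="y", mean_kind="linear", terms=(), family="normal")
        res = FlightModel(df, spec).fit(seed=0)
        grid = pd.DataFrame(index=[0])
        band = mc_confidence_band(res, grid, reps=4000, max_reps=20000, seed=2)
        # profile interval for the mean with sigma2 free: +/- chi2-based
        from scipy import stats

        m, s2 = res.params["p1"], res.params["sigma2"]
        crit = stats.chi2.ppf(0.95, df=2)  # both parameters varied
        halfwidth_profile = np.sqrt(crit * s2 / n)
        lo, hi = band["lower"].iloc[0], band["upper"].iloc[0]
        assert (hi - lo) / 2 == pytest.approx(halfwidth_profile, rel=0.25)

    def test_missing_se_rejected(self, lipid_fit):
        res = FlightResults(
            model=lipid_fit.model,
            params=lipid_fit.params,
            bse=lipid_fit.bse * np.nan,
            llf=lipid_fit.llf,
            converged=True,
            hess_pd=False,
        )
        with pytest.raises(ValueError):
            mc_confidence_band(res, pd.DataFrame({"Wb": [30.0]}))


class TestDeviationSeries:
    def test_perfect_model_classes_on_curve(self):
        fem = generate_females(GeneratorConfig(n_per_treatment=25), seed=23)
        fem["Wlipids"] = 0.086 * fem["Wb"] ** 1.051  # deviates identically 1
        res = FlightModel(fem, get_equation(10)).fit(seed=0)
        classes, curve = deviation_series(res, "Wb")
        # with deviates identically 1, each class mean of Y' equals the mean
        # of the predicted relative curve over that class's members
        per_indiv = np.interp(fem["Wb"], curve["Wb"], curve["relative_effect"])
        edges = np.linspace(fem["Wb"].min(), fem["Wb"].max(), 15)
        idx = np.clip(np.digitize(fem["Wb"], edges[1:-1]), 0, 13)
        expected = [per_indiv[idx == b].mean() for b in range(14) if (idx == b).any()]
        assert np.allclose(classes["mean_deviation"], expected, rtol=1e-3)

    def test_zero_effect_predictor_gives_flat_curve(self, rng):
        fem = generate_females(GeneratorConfig(n_per_treatment=25), seed=29)
        y, _ = draw_response(10, fem, rng)
        fem["Wlipids"] = y
        spec = get_equation(10).with_terms(("Wb", "La"))
        res = FlightModel(fem, spec).fit(
            start_params=np.array([0.086, 1.051, 0.0, 0.022]), n_starts=1, seed=0
        )
        res.params["La"] = 0.0  # evaluate the display at exactly zero effect
        classes, curve = deviation_series(res, "La")
        assert np.allclose(curve["relative_effect"], 1.0, atol=1e-12)

    def test_binned_mass_effect_tracks_power_law(self):
        tab = simulate_refit(7, N=400, reps=1, seed=90)
        assert abs(tab["Wb"].iloc[0] - 0.442) < 0.35  # sanity on the rep
        rng = np.random.default_rng(91)
        fem = generate_females(GeneratorConfig(n_per_treatment=67), seed=91)
        y, _ = draw_response(7, fem, rng)
        fem["Wloss"] = y
        res = FlightModel(fem, get_equation(7)).fit(seed=0)
        classes, curve = deviation_series(res, "Wb")
        ref = (classes["bin_center"] / fem["Wb"].mean()) ** 0.442
        # binned deviations follow the mass power law within MC noise
        resid = classes["mean_deviation"] / ref
        assert np.nanmedian(np.abs(resid - 1)) < 0.25

    def test_unknown_focal_rejected(self, lipid_fit):
        with pytest.raises(ValueError):
            deviation_series(lipid_fit, "Ap")


class TestMeanCurve:
    def test_speed_curve_peaks_at_optimum(self):
        fem = generate_females(GeneratorConfig(n_per_treatment=47), seed=37)
        rng = np.random.default_rng(37)
        y, _ = draw_response(4, fem, rng)
        fem["log10_speed"] = y
        res = FlightModel(fem, get_equation(4)).fit(seed=0)
        curve = mean_curve(res, np.linspace(5, 40, 351))
        t_at_max = curve.loc[curve["mean"].idxmax(), "T"]
        assert t_at_max == pytest.approx(res.params["T0"], abs=0.1)

    def test_distance_zero_crossings_bracket_reported_range(self):
        # published distance equation with plausible covariate means goes to
        # zero in the single digits and the high 30s (degC)
        spec = get_equation(6)
        means = {"La": 9.5, "Ap": 101.3}
        T = np.linspace(0, 45, 4501)
        mu = (
            spec.params["p1"]
            + spec.params["T"] * (T - spec.params["T0"]) ** 2
            + spec.params["La"] * means["La"]
            + spec.params["Ap"] * means["Ap"]
        )
        pos = T[mu > 0]
        assert 4.0 < pos.min() < 10.0
        assert 35.0 < pos.max() < 41.0

    def test_constant_model_flat_curve(self, rng):
        df = pd.DataFrame({"y": rng.normal(2.0, 0.1, 50), "T": np.tile([10.0, 20, 30], 17)[:50]})
        from budwormflight.equations import ModelSpec

        spec = ModelSpec(eq_id=0, response="y", mean_kind="linear", terms=(), family="normal")
        res = FlightModel(df, spec).fit(seed=0)
        curve = mean_curve(res, [10.0, 20.0, 30.0], covariate_means={})
        assert curve["mean"].nunique() == 1

    def test_negative_multiplicative_means_truncated(self):
        fem = generate_females(GeneratorConfig(n_per_treatment=40), seed=41)
        rng = np.random.default_rng(41)
        y, feas = draw_response(6, fem, rng)
        fem["distance_km"] = y
        res = FlightModel(fem.loc[feas], get_equation(6)).fit(seed=0)
        curve = mean_curve(res, np.linspace(0, 45, 91))
        assert curve.attrs["n_truncated"] > 0
        assert (curve["mean"] >= 0).all()
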