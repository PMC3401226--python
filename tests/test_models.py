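"""The five analyses: closed-form Gaussian oracles, joint-likelihood NB
oracle, offset contracts, and factor/offset equivalences."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import optimize, stats

import trapbias as tb
from trapbias.models import THETA_MAX

FLAT = tb.SeasonalProfile((0.2, 0.2, 0.2, 0.2, 0.2))


def _table(dataset):
    return tb.build_analysis_table(dataset)


class TestAnalysisTable:
    def test_complete_dataset(self, field_dataset):
        t = _table(field_dataset)
        assert len(t) == 75
        assert (t["n_traps"] == 4).all()
        assert t["abundance"].sum() == field_dataset.observations["count"].sum()
        assert t.attrs["n_dropped"] == 0
        pcts = t.drop_duplicates("interval").sort_values("interval")["seasonal_pct"]
        assert list(pcts) == [25.0, 49.0, 13.0, 9.0, 4.0]

    def test_after_heavy_loss(self, lossy_dataset):
        t = _table(lossy_dataset)
        assert t["abundance"].sum() == lossy_dataset.surviving()["count"].sum()
        short = t[t["n_traps"] < 4]
        assert set(zip(short["treatment"], short["interval"])) <= {(2, 1), (2, 2), (3, 1), (3, 2)}
        assert t.attrs["n_dropped"] == 75 - len(t)
        assert (t["abundance"] >= 0).all()


class TestM1:
    def test_identical_values_fit_exactly(self, field_params):
        reps = pd.DataFrame(
            {"treatment": np.repeat([1, 2, 3], 5), "replicate": list(range(1, 6)) * 3,
             "standardized_catch": 2.5}
        )
        fit = tb.fit_m1(reps)
        assert np.allclose(fit.log_predictions, np.log(2.5))

    def test_group_means_match_direct_averaging(self, field_dataset):
        reps = tb.summarize_replicates(field_dataset)
        fit = tb.fit_m1(reps)
        oracle = (
            np.log1p(reps["standardized_catch"]).groupby(reps["treatment"]).mean().to_numpy()
        )
        assert np.allclose(fit.treatment_effects, oracle, atol=1e-10)
        assert np.allclose(fit.log_predictions, np.log(np.expm1(oracle)))

    def test_all_zero_catch_floors_prediction(self):
        reps = pd.DataFrame(
            {"treatment": np.repeat([1, 2, 3], 5), "replicate": list(range(1, 6)) * 3,
             "standardized_catch": 0.0}
        )
        fit = tb.fit_m1(reps)
        assert len(fit.flags) == 3
        assert (fit.log_predictions <= np.log(1e-11)).all()


class TestGaussianOffsetModels:
    def test_m2_matches_shifted_response_oracle(self, lossy_dataset):
        """With a known coefficient of one, the offsets can be subtracted from
        the response; per-treatment means of the shifted response are the
        closed-form OLS solution."""
        t = _table(lossy_dataset)
        fit = tb.fit_m2(t)
        shifted = (
            np.log1p(t["abundance"])
            - np.log(t["seasonal_pct"])
            - np.log(t["n_traps"])
        )
        oracle = shifted.groupby(t["treatment"]).mean().to_numpy()
        assert np.allclose(fit.treatment_effects, oracle, atol=1e-10)
        # season-scale prediction: sum of back-transformed per-interval values / traps
        pcts = np.array([25.0, 49.0, 13.0, 9.0, 4.0])
        season = np.array([np.expm1(a + np.log(pcts) + np.log(4)).sum() / 4 for a in oracle])
        assert np.allclose(np.exp(fit.log_predictions), season)

    def test_m2_offset_shift_moves_intercept_only(self, field_dataset):
        """Adding ln 2 to an offset shifts every treatment effect by -ln 2 and
        leaves treatment contrasts untouched (exactly, for the Gaussian fit)."""
        t = _table(field_dataset)
        base = tb.fit_m2(t)
        t2 = t.copy()
        t2["seasonal_pct"] = t2["seasonal_pct"] * 2.0
        shifted = tb.fit_m2(t2)
        assert np.allclose(shifted.treatment_effects, base.treatment_effects - np.log(2), atol=1e-12)
        assert np.allclose(
            np.diff(shifted.treatment_effects), np.diff(base.treatment_effects), atol=1e-12
        )

    def test_m2_doubling_trap_offset_doubles_implied_catch(self, field_dataset):
        """The fitted model predicts proportionally to the trap offset: the
        implied catch at 8 traps is twice that at 4."""
        fit = tb.fit_m2(_table(field_dataset))
        eta4 = fit.treatment_effects + np.log(25.0) + np.log(4)
        eta8 = fit.treatment_effects + np.log(25.0) + np.log(8)
        assert np.allclose(np.exp(eta8), 2 * np.exp(eta4))

    def test_m3_flat_profile_gives_equal_interval_effects(self):
        p = tb.SimulationParams(mean_catch_t1=50.0, site_sd=0.0, trap_sd=0.0, seasonal_profile=FLAT)
        fit = tb.fit_m3(_table(tb.simulate_dataset(p, 8)))
        assert np.all(np.abs(fit.interval_effects) < 0.2)

    def test_m3_contrasts_match_m2_when_factor_absorbs_profile(self, field_dataset):
        """On complete data the free interval factor recovers what the known
        profile offsets encode, so treatment contrasts agree closely."""
        t = _table(field_dataset)
        c2 = np.diff(tb.fit_m2(t).treatment_effects)
        c3 = np.diff(tb.fit_m3(t).treatment_effects)
        assert np.allclose(c2, c3, atol=1e-10)  # same design space: exact for OLS

    def test_m2_rejects_zero_profile_percentages(self, field_params):
        p = tb.SimulationParams(seasonal_profile=tb.SeasonalProfile((1.0, 0, 0, 0, 0)))
        ds = tb.simulate_dataset(p, 3)
        with pytest.raises(tb.ModelFitError):
            tb.fit_m2(tb.build_analysis_table(ds))


def _joint_nb_oracle(y, offset, treatments):
    """Independent oracle: coarse grid over (alpha_1, alpha_2, log theta)
    polished by direct joint maximization of the NB log-likelihood."""
    y = np.asarray(y, float)
    levels = np.unique(treatments)
    X = (np.asarray(treatments)[:, None] == levels[None, :]).astype(float)

    def nll(params):
        alpha, ltheta = params[:-1], params[-1]
        mu = np.exp(X @ alpha + offset)
        th = np.exp(ltheta)
        return -stats.nbinom.logpmf(y, th, th / (th + mu)).sum()

    grid_a = np.linspace(-6, 3, 25)
    grid_t = np.linspace(-2, 8, 21)
    best, best_val = None, np.inf
    for a1 in grid_a:
        for a2 in grid_a:
            for lt in grid_t:
                v = nll(np.array([a1, a2, lt]))
                if v < best_val:
                    best, best_val = np.array([a1, a2, lt]), v
    res = optimize.minimize(nll, best, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
    return res.x[:-1], float(np.exp(res.x[-1]))


def _tiny_table():
    """Fixed 12-row overdispersed fixture with two treatments and unbalanced
    trap effort, small enough for exhaustive likelihood search."""
    table = pd.DataFrame(
        {
            "treatment": [1] * 6 + [2] * 6,
            "replicate": [1, 1, 1, 2, 2, 2] * 2,
            "interval": [1, 2, 3, 4, 5, 1, 1, 2, 2, 4, 3, 5],
            "abundance": [0, 12, 1, 0, 3, 7, 30, 5, 28, 2, 9, 1],
            "n_traps": [2, 4, 4, 3, 4, 4, 4, 4, 3, 4, 4, 2],
        }
    )
    pct = {1: 25.0, 2: 49.0, 3: 13.0, 4: 9.0, 5: 4.0}
    table["seasonal_pct"] = table["interval"].map(pct)
    table.attrs["n_treatments"] = 2
    table.attrs["n_traps_full"] = 4
    table.attrs["percents"] = (25.0, 49.0, 13.0, 9.0, 4.0)
    return table


@pytest.fixture(scope="module")
def tiny_table():
    return _tiny_table()


class TestNegativeBinomial:
    def test_m4_matches_joint_likelihood_oracle(self, tiny_table):
        """The alternating coefficient/theta algorithm lands on the same
        maximum as direct joint likelihood search on a 12-row dataset."""
        fit = tb.fit_m4(tiny_table)
        offset = np.log(tiny_table["seasonal_pct"].to_numpy(float)) + np.log(
            tiny_table["n_traps"].to_numpy(float)
        )
        alpha, theta = _joint_nb_oracle(
            tiny_table["abundance"], offset, tiny_table["treatment"].to_numpy()
        )
        assert np.allclose(fit.treatment_effects, alpha, atol=1e-5)
        assert fit.dispersion == pytest.approx(theta, rel=1e-3)

    def test_m4_flat_profile_equal_counts_recover_total(self):
        """With a flat profile and identical counts the NB fit is saturated in
        the mean: the prediction equals total catch / number of traps."""
        p = tb.SimulationParams(seasonal_profile=FLAT)
        ds = tb.simulate_dataset(p, 1)
        ds.observations["count"] = 3
        fit = tb.fit_m4(tb.build_analysis_table(ds))
        assert fit.dispersion == THETA_MAX  # no over-dispersion left
        assert np.allclose(np.exp(fit.log_predictions), 15.0, rtol=1e-6)

    def test_m5_equal_counts_recover_total(self, field_params):
        ds = tb.simulate_dataset(field_params, 1)
        ds.observations["count"] = 2
        fit = tb.fit_m5(tb.build_analysis_table(ds))
        assert np.allclose(np.exp(fit.log_predictions), 10.0, rtol=1e-6)
        assert np.all(np.abs(fit.interval_effects) < 1e-6)

    @pytest.mark.parametrize("seed", [17, 23, 99])
    def test_reduces_to_poisson_glm_for_poisson_data(self, seed):
        """With no random effects the counts are Poisson; theta runs towards
        its cap and the coefficients approach the Poisson GLM solution."""
        p = tb.SimulationParams(mean_catch_t1=50.0, site_sd=0.0, trap_sd=0.0)
        t = tb.build_analysis_table(tb.simulate_dataset(p, seed))
        fit = tb.fit_m4(t)
        offset = np.log(t["seasonal_pct"].to_numpy(float)) + np.log(t["n_traps"].to_numpy(float))
        X = (t["treatment"].to_numpy()[:, None] == np.array([[1, 2, 3]])).astype(float)
        pois = sm.GLM(t["abundance"].to_numpy(float), X,
                      family=sm.families.Poisson(), offset=offset).fit()
        assert fit.dispersion > 100
        assert np.allclose(fit.treatment_effects, pois.params, atol=1e-2)

    def test_m4_offset_shift_contract(self, field_dataset):
        t = _table(field_dataset)
        base = tb.fit_m4(t)
        t2 = t.copy()
        t2["seasonal_pct"] = t2["seasonal_pct"] * 2.0
        shifted = tb.fit_m4(t2)
        assert np.allclose(shifted.treatment_effects, base.treatment_effects - np.log(2), atol=1e-6)
        assert np.allclose(
            np.diff(shifted.treatment_effects), np.diff(base.treatment_effects), atol=1e-6
        )

    def test_m5_contrasts_match_m4_on_complete_data(self, field_dataset):
        t = _table(field_dataset)
        c4 = np.diff(tb.fit_m4(t).treatment_effects)
        c5 = np.diff(tb.fit_m5(t).treatment_effects)
        assert np.allclose(c4, c5, atol=0.15)  # factor absorbs the profile up to noise

    def test_m5_flat_profile_interval_effects_near_zero(self):
        p = tb.SimulationParams(mean_catch_t1=50.0, site_sd=0.0, trap_sd=0.0, seasonal_profile=FLAT)
        fit = tb.fit_m5(tb.build_analysis_table(tb.simulate_dataset(p, 8)))
        assert np.all(np.abs(fit.interval_effects) < 0.15)

    def test_non_integer_abundance_rejected(self, field_dataset):
        t = _table(field_dataset)
        t["abundance"] = t["abundance"] + 0.5
        with pytest.raises(tb.ModelFitError):
            tb.fit_m4(t)


class TestDegenerateData:
    def test_treatment_without_rows_errors(self, field_dataset):
        t = _table(field_dataset)
        with pytest.raises(tb.ModelFitError):
            tb.fit_m2(t[t["treatment"] != 2])

    def test_zero_catch_treatment_errors_for_nb(self, field_dataset):
        t = _table(field_dataset).copy()
        t.loc[t["treatment"] == 1, "abundance"] = 0
        with pytest.raises(tb.ModelFitError):
            tb.fit_m4(t)

    def test_fit_all_returns_all_five(self, lossy_dataset):
        fits = tb.fit_all(lossy_dataset)
        assert set(fits) == set(tb.MODEL_IDS)
        for f in fits.values():
            assert np.all(np.isfinite(f.log_predictions))
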