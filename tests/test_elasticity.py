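import math

import numpy as np
import pandas as pd
import pytest

from burnflow.elasticity import (CEM_PREDICTORS, attribute_disturbance,
                                 cem_significance, fit_cems, predict_dq_clim,
                                 select_best_cem)


def _annual(n, rng, q_fn, **extra_sd):
    """Annual records with Q generated by q_fn from the climate draws."""
    data = {
        "P": 800 + rng.normal(0, 100, n),
        "PET": 700 + rng.normal(0, 50, n),
        "SWE": 40 + rng.normal(0, 15, n),
        "sigma2_Pm": 900 + rng.normal(0, 200, n),
    }
    df = pd.DataFrame(data)
    anom = df - df.mean()
    df["Q"] = 400 + q_fn(anom)
    return df


class TestFitCems:
    def test_noise_free_identification(self, rng):
        df = _annual(8, rng, lambda a: 0.8 * a["P"])
        fits = {f.model_id: f for f in fit_cems(df)}
        cem1 = fits["CEM1"]
        assert cem1.coefficients["P"] == pytest.approx(0.8, abs=1e-9)
        assert cem1.sse == pytest.approx(0.0, abs=1e-12)

    def test_bic_formula(self, rng):
        df = _annual(6, rng, lambda a: 0.5 * a["P"] + rng.normal(0, 5, 6))
        for f in fit_cems(df):
            if f.fittable:
                assert f.bic == pytest.approx(-2 * f.loglik
                                              + f.k * math.log(f.n), rel=1e-12)

    def test_few_years_only_cem1(self, rng):
        df = _annual(3, rng, lambda a: 0.5 * a["P"])
        fits = {f.model_id: f for f in fit_cems(df)}
        assert fits["CEM1"].fittable
        assert not fits["CEM2"].fittable
        assert "insufficient" in fits["CEM2"].message

    def test_rank_deficient_flagged(self):
        df = pd.DataFrame({"P": [1.0, 1, 1, 1, 1], "PET": [2.0, 2, 2, 2, 2],
                           "SWE": [0.0] * 5, "sigma2_Pm": [1.0] * 5,
                           "Q": [1.0, 2, 3, 4, 5]})
        fits = {f.model_id: f for f in fit_cems(df)}
        assert not fits["CEM2"].fittable

    def test_irrelevant_predictor_penalized_at_small_n(self, rng):
        # pure dP signal: extra predictors can't drop BIC reliably
        wins = 0
        for i in range(50):
            r = np.random.default_rng(900 + i)
            df = _annual(10, r, lambda a: 0.8 * a["P"])
            df["Q"] += r.normal(0, 10, 10)
            best = select_best_cem(fit_cems(df))
            wins += best.model_id == "CEM1"
        assert wins >= 25  # nested rivals only win by fitting noise

    def test_predictor_sets_fixed(self):
        assert CEM_PREDICTORS["CEM4"] == ("P", "SWE")
        assert CEM_PREDICTORS["CEM3"] == ("P", "sigma2_Pm")


class TestSelection:
    def test_single_candidate_returned(self, rng):
        df = _annual(3, rng, lambda a: 0.5 * a["P"])
        best = select_best_cem(fit_cems(df))
        assert best.model_id == "CEM1"

    def test_tie_goes_to_fewer_parameters(self, rng):
        df = _annual(6, rng, lambda a: 0.5 * a["P"] + rng.normal(0, 3, 6))
        fits = fit_cems(df)
        for f in fits:
            if f.fittable:
                f.bic = 100.0  # force a tie
        assert select_best_cem(fits).model_id == "CEM1"

    def test_swe_generated_data_selects_cem4(self):
        hits = 0
        for i in range(60):
            r = np.random.default_rng(1000 + i)
            df = _annual(10, r, lambda a: 0.6 * a["P"] + 2.0 * a["SWE"])
            df["Q"] += r.normal(0, 5, 10)
            hits += select_best_cem(fit_cems(df)).model_id == "CEM4"
        assert hits >= 42  # >= 70% recovery at strong snow signal

    def test_no_fittable_candidate_errors(self, rng):
        df = pd.DataFrame({"P": [1.0] * 5, "Q": [1.0, 2, 3, 4, 5]})
        with pytest.raises(ValueError):
            select_best_cem(fit_cems(df))


class TestSignificance:
    def test_strong_signal_significant_at_n5(self, rng):
        df = _annual(5, rng, lambda a: 0.9 * a["P"])
        df["Q"] += rng.normal(0, 1.0, 5)
        fits = {f.model_id: f for f in fit_cems(df)}
        fit = cem_significance(fits["CEM1"])
        assert fit.test_type == "t" and fit.significant

    def test_cem1_small_n_uses_t(self, rng):
        df = _annual(3, rng, lambda a: 0.5 * a["P"] + rng.normal(0, 1, 3))
        fits = {f.model_id: f for f in fit_cems(df)}
        fit = cem_significance(fits["CEM1"])
        assert fit.test_type == "t"

    def test_multipredictor_uses_f(self, rng):
        df = _annual(8, rng, lambda a: 0.5 * a["P"] - 0.3 * a["PET"]
                     + rng.normal(0, 2, 8))
        fits = {f.model_id: f for f in fit_cems(df)}
        fit = cem_significance(fits["CEM2"])
        assert fit.test_type == "F"

    def test_null_calibration(self):
        rejections = 0
        n_sims = 400
        for i in range(n_sims):
            r = np.random.default_rng(2000 + i)
            df = _annual(8, r, lambda a: r.normal(0, 10, 8))
            fits = {f.model_id: f for f in fit_cems(df)}
            fit = cem_significance(fits["CEM2"], alpha=0.05)
            rejections += bool(fit.significant)
        rate = rejections / n_sims
        assert 0.02 <= rate <= 0.09  # alpha=0.05 within 3.5 binomial sd

    def test_zero_residual_df_untestable(self, rng):
        df = _annual(2, rng, lambda a: 0.5 * a["P"])
        fits = {f.model_id: f for f in fit_cems(df)}
        fit = cem_significance(fits["CEM1"])
        assert fit.test_type == "untestable" and fit.significant is None


class TestPrediction:
    def test_zero_deltas_zero_prediction(self, rng):
        df = _annual(6, rng, lambda a: 0.8 * a["P"])
        best = select_best_cem(fit_cems(df))
        assert predict_dq_clim(best, {k: 0.0 for k in best.predictors}) == 0.0

    def test_linear_arithmetic(self, rng):
        df = _annual(8, rng, lambda a: 0.8 * a["P"])
        fits = {f.model_id: f for f in fit_cems(df)}
        pred = predict_dq_clim(fits["CEM1"], {"P": 50.0})
        assert pred == pytest.approx(0.8 * 50.0, abs=1e-6)

    def test_matches_dot_product_oracle(self, rng):
        df = _annual(9, rng, lambda a: 0.5 * a["P"] + 1.5 * a["SWE"]
                     + rng.normal(0, 2, 9))
        fits = {f.model_id: f for f in fit_cems(df)}
        f4 = fits["CEM4"]
        deltas = {"P": -30.0, "SWE": 12.0}
        oracle = sum(f4.coefficients[p] * deltas[p] for p in f4.predictors)
        assert predict_dq_clim(f4, deltas) == pytest.approx(oracle, rel=1e-12)

    def test_missing_predictor_named(self, rng):
        df = _annual(8, rng, lambda a: 0.5 * a["P"] + a["SWE"])
        fits = {f.model_id: f for f in fit_cems(df)}
        with pytest.raises(KeyError, match="SWE"):
            predict_dq_clim(fits["CEM4"], {"P": 1.0})


class TestAttribution:
    def test_identity(self):
        a = attribute_disturbance(10.0, -5.0, q_pre=100.0)
        assert a.dq_dist == 15.0
        assert a.dq_dist == a.dq_obs - a.dq_clim

    def test_climate_explains_everything(self):
        a = attribute_disturbance(7.5, 7.5, q_pre=100.0)
        assert a.dq_dist == 0.0

    def test_percent_forms(self):
        a = attribute_disturbance(20.0, 5.0, q_pre=200.0)
        assert a.dq_obs_pct == pytest.approx(10.0)
        assert a.dq_dist_pct == pytest.approx(7.5)

    def test_nonpositive_pre_flow_suppresses_percent(self):
        a = attribute_disturbance(10.0, 5.0, q_pre=0.0)
        assert not a.pct_defined and math.isnan(a.dq_dist_pct)
        assert a.flags["q_pre_nonpositive"]

    def test_eligibility_flag(self):
        a = attribute_disturbance(1.0, 0.0, 100.0, bar=22.0, bar_t=19.0)
        b = attribute_disturbance(1.0, 0.0, 100.0, bar=12.0, bar_t=19.0)
        assert a.eligible and not b.eligible
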