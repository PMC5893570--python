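import numpy as np
import pandas as pd
import pytest

import burnflow as bf
from burnflow.synth import (CohortDesign, FireEffectParams, FireEvent,
                            HydroParams, WeatherParams, generate_cohort,
                            generate_daily_weather, generate_fire_event,
                            simulate_flow, simulate_snowpack)


class TestWeather:
    def test_zero_wet_probability_all_dry(self):
        w = generate_daily_weather(WeatherParams(p_wet=0.0), 10, seed=1)
        assert (w["P"] == 0.0).all()

    def test_constant_temperature_degenerate(self):
        w = generate_daily_weather(
            WeatherParams(t_amplitude_c=0.0, t_noise_sd_c=0.0, t_mean_c=5.0),
            10, seed=1)
        assert np.allclose(w["T"], 5.0)

    def test_wet_day_depth_mean(self):
        params = WeatherParams(p_wet=0.3, wet_mean_mm=8.0, gamma_shape=2.0)
        w = generate_daily_weather(params, 30, seed=7)
        wet = w.loc[w["P"] > 0, "P"]
        assert wet.mean() == pytest.approx(8.0, rel=0.05)

    def test_wet_frequency_within_sampling_bounds(self):
        p = 0.3
        w = generate_daily_weather(WeatherParams(p_wet=p), 30, seed=3)
        n = len(w)
        freq = (w["P"] > 0).mean()
        assert abs(freq - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_daylight_deterministic_annual_sinusoid(self):
        w1 = generate_daily_weather(WeatherParams(), 10, seed=1)
        w2 = generate_daily_weather(WeatherParams(), 10, seed=99)
        assert (w1["Hr_day"] == w2["Hr_day"]).all()
        assert w1["Hr_day"].between(0, 24).all()

    def test_persistence_preserves_marginal(self):
        p = 0.35
        w = generate_daily_weather(
            WeatherParams(p_wet=p, wet_persistence=0.5), 40, seed=5)
        assert (w["P"] > 0).mean() == pytest.approx(p, abs=0.03)

    def test_too_short_record_rejected(self):
        with pytest.raises(ValueError):
            generate_daily_weather(WeatherParams(), 5, seed=1)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            WeatherParams(p_wet=1.5)
        with pytest.raises(ValueError):
            WeatherParams(wet_mean_mm=-1.0)


class TestSnowpack:
    def test_always_warm_no_snow(self):
        w = generate_daily_weather(
            WeatherParams(t_mean_c=20.0, t_amplitude_c=2.0, t_noise_sd_c=0.0),
            10, seed=1)
        swe = simulate_snowpack(w, HydroParams())
        assert (swe == 0.0).all()

    def test_hand_computed_melt_recursion(self):
        idx = pd.date_range("2000-01-01", periods=6, freq="D")
        daily = pd.DataFrame({
            "P": [10.0, 0, 0, 0, 0, 0],
            "T": [-5.0, 1, 1, 1, 1, 1],
        }, index=idx)
        hydro = HydroParams(degree_day_mm_per_c=2.0, snow_threshold_c=0.0)
        swe = simulate_snowpack(daily, hydro)
        assert list(swe) == [10.0, 8.0, 6.0, 4.0, 2.0, 0.0]

    def test_zero_degree_day_factor_nondecreasing(self):
        w = generate_daily_weather(WeatherParams(t_mean_c=0.0), 10, seed=2)
        swe = simulate_snowpack(w, HydroParams(degree_day_mm_per_c=0.0))
        assert (np.diff(swe) >= -1e-12).all()

    def test_mass_balance(self):
        w = generate_daily_weather(WeatherParams(t_mean_c=1.0), 12, seed=3)
        hydro = HydroParams()
        swe = simulate_snowpack(w, hydro)
        snow = w.loc[w["T"] < hydro.snow_threshold_c, "P"].sum()
        melt = np.maximum(-np.diff(swe), 0.0).sum()
        assert (swe >= 0).all()
        assert melt <= snow + 1e-9


class TestFireEvent:
    def test_watershed_fractions_scale_with_bar(self):
        ev = generate_fire_event(
            0.20, {"low": 0.5, "moderate": 0.3, "high": 0.2}, "2005-06-01")
        wf = ev.watershed_fractions
        assert wf["low"] == pytest.approx(0.10)
        assert wf["moderate"] == pytest.approx(0.06)
        assert wf["high"] == pytest.approx(0.04)

    def test_zero_bar_zero_areas(self):
        ev = generate_fire_event(0.0, {"low": 1.0}, "2005-06-01")
        assert all(v == 0.0 for v in ev.watershed_fractions.values())

    def test_low_only_mix_no_moderate_high(self):
        ev = generate_fire_event(0.3, {"low": 1.0}, "2005-06-01")
        assert ev.moderate_high_fraction == 0.0

    def test_mix_must_sum_to_one(self):
        with pytest.raises(ValueError):
            generate_fire_event(0.2, {"low": 0.5, "high": 0.4}, "2005-06-01")


class TestFlow:
    @staticmethod
    def _prepared(seed=11, n_years=12):
        daily = generate_daily_weather(WeatherParams(), n_years, seed=seed)
        hydro = HydroParams()
        daily["SWE"] = simulate_snowpack(daily, hydro)
        return daily, hydro

    def test_counterfactual_pairing_of_zero_effect(self):
        daily, hydro = self._prepared()
        fire = generate_fire_event(
            0.30, {"moderate": 0.6, "high": 0.4},
            daily.index[0] + pd.DateOffset(years=6))
        q0, _ = simulate_flow(daily, hydro, fire,
                              FireEffectParams(coefficient=0.0), seed=5)
        q1, truth = simulate_flow(daily, hydro, fire,
                                  FireEffectParams(coefficient=1.0), seed=5)
        pre = daily.index < fire.date
        assert np.allclose(q0[pre], q1[pre])         # identical before fire
        assert (q1[~pre] >= q0[~pre] - 1e-12).all()  # enhanced after
        assert truth["true_dq_mm"] > 0

    def test_below_threshold_no_effect(self):
        daily, hydro = self._prepared()
        fire = generate_fire_event(
            0.10, {"moderate": 0.6, "high": 0.4},
            daily.index[0] + pd.DateOffset(years=6))
        q, truth = simulate_flow(daily, hydro, fire,
                                 FireEffectParams(bar_threshold=0.19), seed=5)
        assert truth["true_dq_mm"] == 0.0 and not truth["active"]

    def test_effect_magnitude_vs_counterfactual(self):
        # coefficient 1.0 and moderate+high watershed fraction 0.30
        # -> post-fire flow 30% above the paired no-fire run
        daily, hydro = self._prepared()
        fire = generate_fire_event(
            0.40, {"moderate": 0.5, "high": 0.25, "low": 0.25},
            daily.index[0] + pd.DateOffset(years=6))
        assert fire.moderate_high_fraction == pytest.approx(0.30)
        q, truth = simulate_flow(daily, hydro, fire,
                                 FireEffectParams(coefficient=1.0), seed=5)
        cf = truth["counterfactual_q"]
        post = (daily.index >= fire.date) & \
            (daily.index < fire.date + pd.DateOffset(years=5))
        ratio = q[post].sum() / cf[post].sum()
        assert ratio == pytest.approx(1.30, abs=1e-9)

    def test_annual_flow_tracks_precipitation_elasticity(self):
        daily, hydro = self._prepared(seed=21, n_years=20)
        hydro_q = HydroParams(flow_noise_sd_mm=0.0, eps_p=2.0, eps_pet=0.0)
        q, _ = simulate_flow(daily, hydro_q, None, None, seed=1)
        years = daily.index.year
        p_ann = daily["P"].groupby(years).sum()
        q_ann = q.groupby(years).sum()
        # log-log regression slope recovers eps_p
        slope = np.polyfit(np.log(p_ann), np.log(q_ann), 1)[0]
        assert slope == pytest.approx(2.0, abs=0.15)

    def test_fire_outside_span_rejected(self):
        daily, hydro = self._prepared()
        fire = generate_fire_event(0.3, {"moderate": 1.0}, "1980-01-01")
        with pytest.raises(ValueError):
            simulate_flow(daily, hydro, fire, FireEffectParams(), seed=1)

    def test_linear_decay_reduces_total_effect(self):
        daily, hydro = self._prepared()
        fire = generate_fire_event(
            0.30, {"moderate": 0.6, "high": 0.4},
            daily.index[0] + pd.DateOffset(years=6))
        _, t_const = simulate_flow(daily, hydro, fire,
                                   FireEffectParams(decay="none"), seed=5)
        _, t_decay = simulate_flow(daily, hydro, fire,
                                   FireEffectParams(decay="linear"), seed=5)
        assert 0 < t_decay["true_dq_mm"] < t_const["true_dq_mm"]


class TestCohort:
    def test_empty_cohort(self):
        assert generate_cohort(0, seed=1) == []

    def test_determinism(self):
        d = CohortDesign(n_years=10, fire_year_index=5)
        c1 = generate_cohort(3, d, seed=77)
        c2 = generate_cohort(3, d, seed=77)
        for a, b in zip(c1, c2):
            pd.testing.assert_frame_equal(a.daily, b.daily)
            assert a.fire.bar == b.fire.bar
            assert a.true_dq_mm == b.true_dq_mm

    def test_bar_grid_ground_truth_partition(self):
        d = CohortDesign(n_years=10, fire_year_index=5,
                         bar_values=[0.05, 0.15, 0.25, 0.35],
                         effect=FireEffectParams(bar_threshold=0.19))
        cohort = generate_cohort(8, d, seed=3)
        for case in cohort:
            if case.fire.bar < 0.19:
                assert case.true_dq_mm == 0.0
            else:
                assert case.true_dq_mm > 0.0

    def test_log_sampling_spans_range(self):
        d = CohortDesign(bar_range=(0.01, 0.40))
        cohort = generate_cohort(50, d, seed=9)
        bars = np.array([c.fire.bar for c in cohort])
        assert bars.min() >= 0.01 and bars.max() <= 0.40
        assert np.median(bars) < 0.12  # right-skewed, like real fire sizes

    def test_climate_diversity_varies_precipitation(self):
        d0 = CohortDesign(climate_diversity=0.0, n_years=10, fire_year_index=5)
        d1 = CohortDesign(climate_diversity=1.0, n_years=10, fire_year_index=5)
        p0 = [c.daily["P"].mean() for c in generate_cohort(8, d0, seed=5)]
        p1 = [c.daily["P"].mean() for c in generate_cohort(8, d1, seed=5)]
        assert np.std(p1) > 2 * np.std(p0)
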