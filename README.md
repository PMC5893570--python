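# burnflow

Statistical detection and attribution of wildland-fire impacts on river flow.

After a large fire, annual river flow from a burned watershed often changes —
but so does the climate. `burnflow` implements, for hydrologists and
environmental statisticians, a four-step framework that decides whether a
fire disturbed a watershed's flow and how much of the observed 5-year change
in mean annual flow is attributable to the fire rather than to climate
variability:

1. **Change point** — a change-point model slides through the 120 months of
   flow around the fire and evaluates the Lepage statistic
   `L = U*² + M²` (standardized Mann–Whitney rank-sum for location, Mood
   statistic for scale) at every split; the null of no change is rejected
   when `L_max` exceeds a permutation critical value `h_t` *and* the change
   falls within a year after the fire.
2. **Double-mass / Chow** — cumulative flow `Q_cum` is regressed on
   cumulative precipitation `P_cum`; the Chow test
   `F = [(SSE₀ − (SSE₁+SSE₂))/K] / [(SSE₁+SSE₂)/(n−2K)]` checks for a
   structural break in the water-yield ratio exactly at the fire date.
3. **Relative influence** — a gradient-boosted regression of the flow change
   dQ on fire, geometry, topography, land-cover and climate variables, with
   two random probe variables as the noise floor; refits on subsets with an
   increasing lower limit on the burned-area ratio (BAR) locate the critical
   threshold BAR_t above which burn severity influences flow.
4. **Elasticity & attribution** — candidate climate-elasticity models
   (dQ ~ dP; +dPET; +dσ²_Pm; +dSWE) are fitted on pre-fire annual anomalies,
   selected by BIC, and the fire's share of the change is the residual
   identity **ΔQ_dist = ΔQ_obs − ΔQ_clim**.

A synthetic watershed generator (stochastic weather, degree-day snowpack,
elasticity-driven flow, threshold-activated fire enhancement with recorded
ground truth) makes the whole pipeline testable end to end without any
external datasets. See `docs/methods.md` for the model details and choices.

## Worked example

```python
import pandas as pd
import burnflow as bf

# one synthetic watershed: 12 years of daily weather, snow and flow,
# with a fire burning 30% of the watershed at year 6
daily = bf.generate_daily_weather(bf.WeatherParams(), n_years=12, seed=42)
hydro = bf.HydroParams()
daily["SWE"] = bf.simulate_snowpack(daily, hydro)
fire = bf.generate_fire_event(
    0.30, {"unburned": .10, "low": .30, "moderate": .40, "high": .15,
           "greenness": .05},
    daily.index[0] + pd.DateOffset(years=6))
daily["Q"], truth = bf.simulate_flow(daily, hydro, fire,
                                     bf.FireEffectParams(), seed=43)

report = bf.analyze_case(daily, fire, n_perm=199, seed=7)
a = report.attribution
print(report.step2.break_detected, report.best_cem.model_id)
print(f"dQ_obs {a.dq_obs:.1f}  dQ_clim {a.dq_clim:.1f}  dQ_dist {a.dq_dist:.1f} mm/yr")
print(f"truth: {truth['true_dq_mm']:.1f} mm/yr")
```

prints

```
True CEM1
dQ_obs -30.3  dQ_clim -102.9  dQ_dist 72.6 mm/yr
truth: 56.0 mm/yr
```

The injected fire effect is +56.0 mm/yr (the simulator's counterfactual
ground truth). The double-mass curve breaks at the fire date and the
precipitation-only elasticity model CEM1 wins the BIC comparison. The
observed change is *negative* (−30.3 mm/yr) because the post-fire years
happened to be much drier — the climate alone would have cut flow by
102.9 mm/yr — yet the attribution identity recovers a positive fire
contribution of +72.6 mm/yr: the masking situation the framework is built
to untangle.

The `examples/` directory has one short script per capability: synthetic
generation, change-point detection, double-mass analysis, influence and the
BAR_t scan, attribution, and the full cohort pipeline
(`python examples/06_full_pipeline.py`).

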