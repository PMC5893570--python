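"""Synthetic watershed cohorts with known ground truth.

Generates the inputs the detection/attribution framework consumes —
daily precipitation, temperature, daylight hours, snow water equivalent
and river flow for a gauged watershed, plus a fire event with burned
area and severity composition — with the true fire effect on flow
recorded alongside, so that recovery of that effect by the statistical
pipeline is directly measurable.

The weather generator is deliberately simple: seasonal wet-day
occurrence (optionally persistent), gamma-distributed wet-day depths, a
sinusoidal temperature climate with Gaussian daily noise, and a
deterministic daylight-hours sinusoid. Snowpack follows a degree-day
model. Annual flow responds to annual precipitation and potential
evapotranspiration through prescribed power-law elasticities, routed
within the year by a linear-reservoir recession so monthly flow has a
realistic seasonal shape. A fire multiplies flow by
(1 + c * f_mh) for a configurable number of post-fire years, where f_mh
is the watershed-area fraction burned at moderate or high severity —
and only when the burned-area ratio reaches the activation threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import WatershedAttrs, hamon_pet

__all__ = [
    "WeatherParams",
    "HydroParams",
    "FireEffectParams",
    "FireEvent",
    "SyntheticCase",
    "CohortDesign",
    "generate_daily_weather",
    "simulate_snowpack",
    "simulate_flow",
    "generate_fire_event",
    "generate_cohort",
]

_SEASON_OF_MONTH = np.array([0, 0, 1, 1, 1, 2, 2, 2, 3, 3, 3, 0])  # DJF MAM JJA SON
_SEVERITY_CLASSES = ("unburned", "low", "moderate", "high", "greenness")


@dataclass(frozen=True)
class WeatherParams:
    """Stochastic daily weather configuration.

    ``p_wet`` is the wet-day probability, a scalar or four seasonal
    values (DJF, MAM, JJA, SON). Wet-day depths are gamma with the given
    mean (mm) and shape. Temperature is an annual sinusoid (mean,
    amplitude, peaking in late July) plus Gaussian daily noise.
    ``daylight_amplitude_h`` controls the daylight sinusoid around 12 h
    (a latitude proxy: 0 at the equator, larger poleward).
    ``wet_persistence`` adds first-order wet/dry persistence while
    preserving the marginal wet-day probability (0 = independent days).
    """

    p_wet: float | Sequence[float] = 0.35
    wet_mean_mm: float = 7.0
    gamma_shape: float = 0.75
    t_mean_c: float = 8.0
    t_amplitude_c: float = 11.0
    t_noise_sd_c: float = 3.0
    daylight_amplitude_h: float = 3.0
    wet_persistence: float = 0.0

    def __post_init__(self) -> None:
        p = np.atleast_1d(np.asarray(self.p_wet, dtype=float))
        if p.size not in (1, 4):
            raise ValueError("p_wet must be a scalar or four seasonal values")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("wet-day probabilities must lie in [0, 1]")
        if self.wet_mean_mm <= 0:
            raise ValueError("mean wet-day depth must be positive")
        if self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")
        if self.t_noise_sd_c < 0 or self.t_amplitude_c < 0:
            raise ValueError("temperature amplitude and noise sd must be >= 0")
        if not 0.0 <= self.wet_persistence < 1.0:
            raise ValueError("wet_persistence must lie in [0, 1)")

    def seasonal_p_wet(self) -> np.ndarray:
        p = np.atleast_1d(np.asarray(self.p_wet, dtype=float))
        return np.repeat(p, 4) if p.size == 1 else p


@dataclass(frozen=True)
class HydroParams:
    """Flow-generation configuration.

    ``eps_p`` and ``eps_pet`` are the elasticities of annual flow to
    annual precipitation and PET (dimensionless; typical basins have
    eps_p in 1-3 and eps_pet <= 0). ``runoff_ratio`` sets the reference
    annual flow as a fraction of reference precipitation. The degree-day
    factor (mm per deg C per day) and snow/rain threshold (deg C) drive
    the snowpack model; ``recession`` is the linear-reservoir storage
    carry-over per day in (0, 1). ``flow_noise_sd_mm`` is the sd of the
    annual flow perturbation in mm.
    """

    eps_p: float = 2.0
    eps_pet: float = -0.6
    runoff_ratio: float = 0.4
    degree_day_mm_per_c: float = 2.5
    snow_threshold_c: float = 0.0
    recession: float = 0.95
    flow_noise_sd_mm: float = 25.0

    def __post_init__(self) -> None:
        if not 0.0 < self.recession < 1.0:
            raise ValueError("recession must lie in (0, 1)")
        if self.degree_day_mm_per_c < 0:
            raise ValueError("degree-day factor must be >= 0")
        if not 0.0 < self.runoff_ratio <= 1.0:
            raise ValueError("runoff ratio must lie in (0, 1]")
        if self.flow_noise_sd_mm < 0:
            raise ValueError("flow noise sd must be >= 0")


@dataclass(frozen=True)
class FireEffectParams:
    """Fire-induced flow enhancement.

    Flow after the fire is multiplied by (1 + coefficient * f_mh), with
    f_mh the moderate+high severity watershed-area fraction, for
    ``duration_years`` — but only when the burned-area ratio reaches
    ``bar_threshold``. With ``decay='linear'`` the enhancement shrinks
    linearly to zero over the duration instead of holding constant.
    """

    bar_threshold: float = 0.19
    coefficient: float = 1.0
    duration_years: float = 5.0
    decay: str = "none"

    def __post_init__(self) -> None:
        if not 0.0 <= self.bar_threshold <= 1.0:
            raise ValueError("BAR activation threshold must lie in [0, 1]")
        if self.duration_years < 1.0:
            raise ValueError("effect duration must be at least 1 year")
        if self.decay not in ("none", "linear"):
            raise ValueError("decay must be 'none' or 'linear'")


@dataclass(frozen=True)
class FireEvent:
    """A fire: date, burned-area ratio and severity composition.

    ``severity_mix`` gives fractions *of the burned area* in each
    severity class (unburned/underburned, low, moderate, high, increased
    greenness); they must sum to 1. Watershed-area fractions per class
    are the mix scaled by BAR.
    """

    date: pd.Timestamp
    bar: float
    severity_mix: Mapping[str, float]
    burned_area_km2: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.bar <= 1.0:
            raise ValueError("BAR must lie in [0, 1]")
        total = float(sum(self.severity_mix.values()))
        if any(v < 0 for v in self.severity_mix.values()):
            raise ValueError("severity fractions must be non-negative")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"severity fractions must sum to 1, got {total}")

    @property
    def watershed_fractions(self) -> dict[str, float]:
        """Per-class burned fraction of the whole watershed (mix * BAR)."""
        return {k: float(v) * self.bar for k, v in self.severity_mix.items()}

    @property
    def moderate_high_fraction(self) -> float:
        """Watershed-area fraction burned at moderate or high severity."""
        wf = self.watershed_fractions
        return wf.get("moderate", 0.0) + wf.get("high", 0.0)


def generate_fire_event(bar: float, severity_mix: Mapping[str, float],
                        date) -> FireEvent:
    """Build a validated :class:`FireEvent` from its components."""
    return FireEvent(date=pd.Timestamp(date), bar=float(bar),
                     severity_mix=dict(severity_mix))


# ---------------------------------------------------------------------------
# weather / snow / flow simulation
# ---------------------------------------------------------------------------

def generate_daily_weather(params: WeatherParams, n_years: int,
                           seed: int | None = None,
                           start: str = "2000-01-01") -> pd.DataFrame:
    """Simulate daily P (mm), T (deg C) and daylight hours Hr_day.

    At least 10 years are required: the downstream pipeline needs two
    full 5-year windows around a fire date.
    """
    if n_years < 10:
        raise ValueError(
            f"n_years must be >= 10 (two 5-year windows needed), got {n_years}"
        )
    rng = np.random.default_rng(seed)
    index = pd.date_range(start, periods=365 * n_years, freq="D")
    doy = index.dayofyear.to_numpy()
    month = index.month.to_numpy()

    p_daily = params.seasonal_p_wet()[_SEASON_OF_MONTH[month - 1]]
    if params.wet_persistence == 0.0:
        wet = rng.random(len(index)) < p_daily
    else:
        # two-state chain with lag-1 correlation rho preserving marginals:
        # P(wet|wet) = p + rho(1-p), P(wet|dry) = p(1-rho)
        rho = params.wet_persistence
        u = rng.random(len(index))
        wet = np.empty(len(index), dtype=bool)
        wet[0] = u[0] < p_daily[0]
        for i in range(1, len(index)):
            p = p_daily[i]
            p_cond = p + rho * (1.0 - p) if wet[i - 1] else p * (1.0 - rho)
            wet[i] = u[i] < p_cond
    depths = rng.gamma(params.gamma_shape,
                       params.wet_mean_mm / params.gamma_shape, len(index))
    precip = np.where(wet, depths, 0.0)

    phase = 2.0 * np.pi * (doy - 202) / 365.0  # warmest around 21 July
    temp = (params.t_mean_c + params.t_amplitude_c * np.cos(phase)
            + rng.normal(0.0, params.t_noise_sd_c, len(index)))
    daylight = np.clip(
        12.0 + params.daylight_amplitude_h
        * np.cos(2.0 * np.pi * (doy - 172) / 365.0), 0.0, 24.0)

    return pd.DataFrame({"P": precip, "T": temp, "Hr_day": daylight}, index=index)


def simulate_snowpack(daily: pd.DataFrame, params: HydroParams) -> pd.Series:
    """Degree-day snowpack: accumulate below threshold, melt above.

    Precipitation on days with T < threshold enters the pack; on warmer
    days the pack loses min(SWE, ddf * (T - threshold)). SWE is always
    >= 0 and total melt cannot exceed total snowfall.
    """
    t = daily["T"].to_numpy()
    p = daily["P"].to_numpy()
    thr = params.snow_threshold_c
    ddf = params.degree_day_mm_per_c
    snow = np.where(t < thr, p, 0.0)
    melt_pot = np.where(t > thr, ddf * (t - thr), 0.0)
    swe = np.empty(len(t))
    pack = 0.0
    for i in range(len(t)):
        pack += snow[i]
        pack -= min(pack, melt_pot[i])
        swe[i] = pack
    return pd.Series(swe, index=daily.index, name="SWE")


def _fire_multiplier(index: pd.DatetimeIndex, fire: FireEvent,
                     effect: FireEffectParams) -> np.ndarray:
    """Daily flow multiplier implementing the fire enhancement."""
    mult = np.ones(len(index))
    if fire.bar < effect.bar_threshold:
        return mult
    boost = effect.coefficient * fire.moderate_high_fraction
    if boost == 0.0:
        return mult
    t_years = (index - fire.date).days / 365.25
    active = (t_years >= 0) & (t_years < effect.duration_years)
    if effect.decay == "linear":
        mult[active] = 1.0 + boost * (1.0 - t_years[active] / effect.duration_years)
    else:
        mult[active] = 1.0 + boost
    return mult


def simulate_flow(daily: pd.DataFrame, hydro: HydroParams, fire: FireEvent | None,
                  effect: FireEffectParams | None = None,
                  seed: int | None = None) -> tuple[pd.Series, dict]:
    """Simulate daily flow Q (mm) responding to climate and fire.

    Expected annual flow follows the elasticity relation

        Q_y = r * P_ref * (P_y / P_ref)^eps_p * (PET_y / PET_ref)^eps_pet

    about the series-mean reference climate, perturbed by Gaussian
    annual noise; the within-year shape routes rain + snowmelt through a
    linear reservoir. The fire multiplier of :func:`_fire_multiplier` is
    applied afterwards, so the pre-multiplier series is the exact
    no-fire counterfactual under the same seed.

    Returns the flow series and a ground-truth dict with the
    counterfactual series and, when 5 post-fire years exist, the true
    effect in mm/yr and percent of pre-fire flow.
    """
    if "SWE" not in daily.columns:
        raise ValueError("simulate snowpack first: daily record lacks SWE")
    if fire is not None:
        if not (daily.index[0] <= fire.date <= daily.index[-1]):
            raise ValueError(f"fire date {fire.date.date()} outside series span")
    rng = np.random.default_rng(seed)
    t = daily["T"].to_numpy()
    p = daily["P"].to_numpy()
    swe = daily["SWE"].to_numpy()
    thr = hydro.snow_threshold_c
    rain = np.where(t >= thr, p, 0.0)
    # melt on day i = pack decrease; accumulation days give 0
    melt = np.maximum(np.concatenate([[0.0], swe[:-1] - swe[1:]]), 0.0)
    water_in = rain + melt

    # linear reservoir shape
    shaped = np.empty(len(p))
    storage = water_in[:30].mean() / (1.0 - hydro.recession)  # warm start
    for i in range(len(p)):
        storage += water_in[i]
        out = (1.0 - hydro.recession) * storage
        storage -= out
        shaped[i] = out

    pet = hamon_pet(daily["T"], daily["Hr_day"])
    years = daily.index.year.to_numpy()
    year_ids = np.unique(years)
    p_ann = np.array([p[years == y].sum() for y in year_ids])
    pet_ann = np.array([np.asarray(pet)[years == y].sum() for y in year_ids])
    p_ref, pet_ref = p_ann.mean(), pet_ann.mean()
    q_ref = hydro.runoff_ratio * p_ref
    q_ann = q_ref * (p_ann / p_ref) ** hydro.eps_p \
        * (pet_ann / pet_ref) ** hydro.eps_pet
    q_ann = np.maximum(q_ann + rng.normal(0.0, hydro.flow_noise_sd_mm,
                                          len(year_ids)), 1e-6)

    q = shaped.copy()
    for y, target in zip(year_ids, q_ann):
        mask = years == y
        total = shaped[mask].sum()
        q[mask] = shaped[mask] * (target / total) if total > 0 else target / mask.sum()

    counterfactual = pd.Series(q, index=daily.index, name="Q")
    truth: dict = {"counterfactual_q": counterfactual}
    if fire is not None and effect is not None:
        mult = _fire_multiplier(daily.index, fire, effect)
        q = q * mult
        post = (daily.index >= fire.date) & \
            (daily.index < fire.date + pd.DateOffset(years=5))
        pre = (daily.index < fire.date) & \
            (daily.index >= fire.date - pd.DateOffset(years=5))
        if post.sum() >= 5 * 365 - 3 and pre.sum() >= 5 * 365 - 3:
            dq_mm = float((q[post] - counterfactual.to_numpy()[post]).sum() / 5.0)
            q_pre_ann = float(counterfactual.to_numpy()[pre].sum() / 5.0)
            truth["true_dq_mm"] = dq_mm
            truth["true_dq_pct"] = 100.0 * dq_mm / q_pre_ann
            truth["q_pre_mm"] = q_pre_ann
        truth["active"] = bool(fire.bar >= effect.bar_threshold
                               and effect.coefficient
                               * fire.moderate_high_fraction > 0)
    return pd.Series(q, index=daily.index, name="Q"), truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticCase:
    """One synthetic watershed with its ground truth."""

    case_id: str
    attrs: WatershedAttrs
    daily: pd.DataFrame
    fire: FireEvent
    true_dq_mm: float
    true_dq_pct: float
    true_elasticities: dict
    active_effect: bool


@dataclass(frozen=True)
class CohortDesign:
    """Study-condition configuration for a synthetic cohort.

    ``bar_range`` spans burned-area ratios across cases; the default
    ``bar_sampling='log'`` draws them log-uniformly, reproducing the
    strong right skew of real fire sizes (most fires burn a small
    fraction of their watershed; the cohort median lands near 6% BAR).
    ``bar_sampling='linear'`` spreads them evenly, or pass an explicit
    ``bar_values`` grid. ``severity_mix`` is the mean burned-area
    composition; per-case mixes are Dirichlet-jittered around it.

    ``climate_diversity`` scales per-case jitter of the weather
    parameters (wet-day depth, wet-day probability, temperature level)
    so watersheds differ in mean climate and interannual variability as
    a real cohort does; 0 gives every case the identical climate
    configuration. ``precip_post_factor`` scales post-fire daily
    precipitation to emulate a climate shift concurrent with the fire
    (1 = stationary climate); it applies to the counterfactual too, so
    ground-truth fire effects are unaffected.
    """

    n_years: int = 12
    fire_year_index: int = 6
    bar_range: tuple[float, float] = (0.01, 0.40)
    bar_sampling: str = "log"
    bar_values: Sequence[float] | None = None
    climate_diversity: float = 1.0
    severity_mix: Mapping[str, float] = field(default_factory=lambda: {
        "unburned": 0.15, "low": 0.35, "moderate": 0.30,
        "high": 0.15, "greenness": 0.05})
    mix_concentration: float = 60.0
    weather: WeatherParams = field(default_factory=WeatherParams)
    hydro: HydroParams = field(default_factory=HydroParams)
    effect: FireEffectParams = field(default_factory=FireEffectParams)
    precip_post_factor: float = 1.0
    start: str = "2000-01-01"

    def __post_init__(self) -> None:
        if self.fire_year_index < 5 or self.n_years - self.fire_year_index < 5:
            raise ValueError("need at least 5 years on each side of the fire")
        if self.bar_sampling not in ("log", "linear"):
            raise ValueError("bar_sampling must be 'log' or 'linear'")
        if self.climate_diversity < 0:
            raise ValueError("climate_diversity must be >= 0")


def _sample_attrs(rng: np.random.Generator) -> WatershedAttrs:
    area = float(np.exp(rng.uniform(np.log(30.0), np.log(2000.0))))
    compact = float(rng.uniform(1.05, 1.8))
    perimeter = compact * 2.0 * np.sqrt(np.pi * area)
    cover = rng.dirichlet([7.0, 0.5, 0.5, 2.0])
    return WatershedAttrs(
        area_km2=area, perimeter_km=float(perimeter),
        elevation_m=float(rng.uniform(200.0, 2500.0)),
        slope=float(rng.uniform(0.02, 0.5)),
        land_cover={"forest": cover[0], "barren": cover[1],
                    "urban": cover[2], "other": cover[3]},
    )


def _jitter_weather(base: WeatherParams, scale: float,
                    rng: np.random.Generator) -> WeatherParams:
    """Per-case climate diversity: vary mean depth, wetness and warmth."""
    if scale == 0.0:
        return base
    p = base.seasonal_p_wet()
    p = np.clip(p * np.exp(rng.normal(0.0, 0.25 * scale)), 0.02, 0.95)
    return WeatherParams(
        p_wet=tuple(float(v) for v in p),
        wet_mean_mm=base.wet_mean_mm * float(np.exp(rng.normal(0.0, 0.3 * scale))),
        gamma_shape=base.gamma_shape,
        t_mean_c=base.t_mean_c + float(rng.normal(0.0, 4.0 * scale)),
        t_amplitude_c=base.t_amplitude_c,
        t_noise_sd_c=base.t_noise_sd_c,
        daylight_amplitude_h=base.daylight_amplitude_h,
        wet_persistence=base.wet_persistence,
    )


def _make_case(case_id: str, design: CohortDesign, bar: float,
               seed_seq: np.random.SeedSequence) -> SyntheticCase:
    seeds = seed_seq.generate_state(3)
    rng = np.random.default_rng(seed_seq.spawn(1)[0])
    attrs = _sample_attrs(rng)
    weather = _jitter_weather(design.weather, design.climate_diversity, rng)
    daily = generate_daily_weather(weather, design.n_years,
                                   seed=int(seeds[0] % 2**31), start=design.start)
    fire_date = daily.index[0] + pd.DateOffset(years=design.fire_year_index)
    if design.precip_post_factor != 1.0:
        post = daily.index >= fire_date
        daily.loc[post, "P"] *= design.precip_post_factor
    mix_mean = np.array([design.severity_mix[c] for c in _SEVERITY_CLASSES])
    mix = rng.dirichlet(np.maximum(mix_mean * design.mix_concentration, 1e-3))
    fire = generate_fire_event(bar, dict(zip(_SEVERITY_CLASSES, mix)), fire_date)
    daily["SWE"] = simulate_snowpack(daily, design.hydro)
    q, truth = simulate_flow(daily, design.hydro, fire, design.effect,
                             seed=int(seeds[1] % 2**31))
    daily["Q"] = q
    return SyntheticCase(
        case_id=case_id, attrs=attrs, daily=daily, fire=fire,
        true_dq_mm=truth.get("true_dq_mm", 0.0),
        true_dq_pct=truth.get("true_dq_pct", 0.0),
        true_elasticities={"eps_p": design.hydro.eps_p,
                           "eps_pet": design.hydro.eps_pet},
        active_effect=truth.get("active", False),
    )


def generate_cohort(n: int, design: CohortDesign | None = None,
                    seed: int | None = None) -> list[SyntheticCase]:
    """Generate ``n`` synthetic watersheds under one design.

    Burned-area ratios are drawn log-uniformly (or spread evenly) over
    ``design.bar_range``, or taken from ``design.bar_values``, cycled.
    All randomness descends from ``seed``; identical seeds give
    identical cohorts.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    design = design or CohortDesign()
    root = np.random.SeedSequence(seed)
    children = root.spawn(max(n, 1) + 1)
    if design.bar_values is not None:
        bars = [float(design.bar_values[i % len(design.bar_values)])
                for i in range(n)]
    elif design.bar_sampling == "log":
        bar_rng = np.random.default_rng(children[-1])
        lo, hi = design.bar_range
        bars = list(np.exp(bar_rng.uniform(np.log(lo), np.log(hi), n)))
    else:
        lo, hi = design.bar_range
        bars = list(np.linspace(lo, hi, n)) if n > 1 else [0.5 * (lo + hi)]
    return [_make_case(f"ws{i:03d}", design, bars[i], children[i])
            for i in range(n)]
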