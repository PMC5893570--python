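"""Derived variables consumed by the disturbance-detection framework.

This module computes the physical covariates that sit between raw
watershed records (daily flow and climate) and the statistical steps:

* Hamon potential evapotranspiration (PET) from air temperature and
  daylight hours,
* the Gravelius compactness coefficient describing watershed plan shape,
* the burned-area ratio (BAR) of a fire event,
* 5-year pre/post-fire window aggregates (mean annual flow and climate,
  monthly precipitation variance) and their post-minus-pre deltas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "WatershedAttrs",
    "WindowSummary",
    "magnus_saturation_vapor_pressure",
    "hamon_pet",
    "gravelius_compactness",
    "burned_area_ratio",
    "monthly_from_daily",
    "window_summary",
    "annual_records",
]

#: Months aggregated on each side of the fire date (5 years).
WINDOW_MONTHS = 60


# ---------------------------------------------------------------------------
# watershed attributes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WatershedAttrs:
    """Static geometry, topography and land cover of one watershed.

    Parameters
    ----------
    area_km2:
        Drainage area A in km^2. Must exceed 10 km^2 (small headwater
        basins with unreliable gauging are excluded from the analysis).
    perimeter_km:
        Watershed perimeter Pm in km.
    elevation_m:
        Mean elevation in metres.
    slope:
        Mean slope as a fraction (rise over run).
    land_cover:
        Fractions of forest, barren, urban and other cover; must sum to 1.
    """

    area_km2: float
    perimeter_km: float
    elevation_m: float = 500.0
    slope: float = 0.1
    land_cover: Mapping[str, float] = field(
        default_factory=lambda: {"forest": 0.7, "barren": 0.05, "urban": 0.05, "other": 0.2}
    )

    def __post_init__(self) -> None:
        if self.area_km2 <= 10.0:
            raise ValueError(f"drainage area must exceed 10 km^2, got {self.area_km2}")
        if self.perimeter_km <= 0:
            raise ValueError("perimeter must be positive")
        total = float(sum(self.land_cover.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"land-cover fractions must sum to 1, got {total}")
        if any(v < 0 for v in self.land_cover.values()):
            raise ValueError("land-cover fractions must be non-negative")

    @property
    def compactness(self) -> float:
        """Gravelius compactness coefficient C (1 = circular)."""
        return gravelius_compactness(self.perimeter_km, self.area_km2)


# ---------------------------------------------------------------------------
# point formulas
# ---------------------------------------------------------------------------

def magnus_saturation_vapor_pressure(t_c):
    """Saturation vapor pressure (kPa) at air temperature ``t_c`` (deg C).

    Magnus form: e_sat = 0.6108 * exp(17.27 T / (T + 237.3)).
    """
    t_c = np.asarray(t_c, dtype=float)
    return 0.6108 * np.exp(17.27 * t_c / (t_c + 237.3))


def hamon_pet(t_c, daylight_h, esat=magnus_saturation_vapor_pressure):
    """Hamon potential evapotranspiration in mm per day.

    PET = 29.8 * Hr_day * e_sat(T) / (T + 273.2), with Hr_day the number
    of daylight hours and e_sat the saturation vapor pressure in kPa.
    The formula is monotone increasing in both T and Hr_day and vanishes
    with zero daylight.

    Parameters
    ----------
    t_c:
        Mean air temperature in deg C (scalar or array).
    daylight_h:
        Daylight hours (scalar or array, 0-24).
    esat:
        Saturation vapor pressure function of T (kPa); the Magnus form
        by default.
    """
    t_c = np.asarray(t_c, dtype=float)
    daylight_h = np.asarray(daylight_h, dtype=float)
    if np.any(t_c <= -273.2):
        raise ValueError("temperature at or below -273.2 C: Hamon denominator non-positive")
    pet = 29.8 * daylight_h * esat(t_c) / (t_c + 273.2)
    return pet if pet.ndim else float(pet)


def gravelius_compactness(perimeter_km: float, area_km2: float) -> float:
    """Gravelius compactness C = Pm / (2 sqrt(pi A)).

    C is the ratio of the watershed perimeter to the perimeter of a
    circle of the same area; C = 1 for a circle and grows with
    elongation. Values below 1 are geometrically impossible and signal
    inconsistent perimeter/area inputs (a warning is emitted).
    """
    if perimeter_km <= 0 or area_km2 <= 0:
        raise ValueError("perimeter and area must be positive")
    c = perimeter_km / (2.0 * np.sqrt(np.pi * area_km2))
    if c < 1.0 - 1e-12:
        warnings.warn(
            f"compactness {c:.4f} < 1: perimeter/area inconsistent", stacklevel=2
        )
    return float(c)


def burned_area_ratio(event, attrs: WatershedAttrs) -> float:
    """Burned-area ratio BAR = burned area / drainage area, in [0, 1].

    ``event`` may carry an explicit ``burned_area_km2``; otherwise its
    stored ``bar`` fraction is returned unchanged.
    """
    burned = getattr(event, "burned_area_km2", None)
    if burned is not None:
        if burned < 0:
            raise ValueError("burned area must be non-negative")
        if burned > attrs.area_km2:
            raise ValueError(
                f"burned area {burned} km^2 exceeds drainage area {attrs.area_km2} km^2"
            )
        return float(burned / attrs.area_km2)
    return float(event.bar)


# ---------------------------------------------------------------------------
# window aggregation
# ---------------------------------------------------------------------------

#: Daily columns summed to monthly totals; all others are averaged.
_SUM_COLS = ("P", "Q", "PET")


def monthly_from_daily(daily: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a date-indexed daily record to calendar months.

    Fluxes (P, Q, PET) are summed to monthly totals in mm; states
    (T, SWE, Hr_day) are averaged.
    """
    if not isinstance(daily.index, pd.DatetimeIndex):
        raise TypeError("daily record must have a DatetimeIndex")
    grouper = daily.groupby(daily.index.to_period("M"))
    out = {}
    for col in daily.columns:
        out[col] = grouper[col].sum() if col in _SUM_COLS else grouper[col].mean()
    return pd.DataFrame(out)


@dataclass(frozen=True)
class WindowSummary:
    """5-year pre/post-fire aggregates and their deltas.

    ``pre`` and ``post`` map variable names (P, PET, SWE, Q in mm per
    year; sigma2_Pm in mm^2) to window values; ``delta`` is post minus
    pre in the same units and ``delta_pct`` is 100*delta/pre.
    ``undefined_pct`` lists variables whose pre-window mean is zero, for
    which the percent form is reported as NaN rather than dropped.
    """

    pre: Mapping[str, float]
    post: Mapping[str, float]
    delta: Mapping[str, float]
    delta_pct: Mapping[str, float]
    undefined_pct: tuple = ()
    fire_month: pd.Period | None = None


def _window_values(monthly: pd.DataFrame) -> dict:
    """Aggregate one 60-month block to annual-scale summary variables."""
    out = {}
    n_years = len(monthly) / 12.0
    for col in ("P", "PET", "Q"):
        if col in monthly:
            out[col] = float(monthly[col].sum() / n_years)
    if "SWE" in monthly:
        out["SWE"] = float(monthly["SWE"].mean())
    if "P" in monthly:
        out["sigma2_Pm"] = float(monthly["P"].var(ddof=1))
    return out


def window_summary(monthly: pd.DataFrame, fire_date) -> WindowSummary:
    """Summarise the 60 months before and after a fire date.

    The fire month itself belongs to the post window (the change-point
    rule looks for disturbance in the year *following* the fire).

    Parameters
    ----------
    monthly:
        PeriodIndex('M')-indexed frame with columns among P, PET, SWE, Q
        (monthly totals for fluxes, monthly means for SWE).
    fire_date:
        Anything convertible to a monthly period.
    """
    if not isinstance(monthly.index, pd.PeriodIndex):
        raise TypeError("monthly record must have a PeriodIndex (freq='M')")
    fire_month = pd.Period(fire_date, freq="M")
    n_pre = int((monthly.index < fire_month).sum())
    n_post = int((monthly.index >= fire_month).sum())
    if n_pre < WINDOW_MONTHS or n_post < WINDOW_MONTHS:
        raise ValueError(
            f"need {WINDOW_MONTHS} months on each side of {fire_month}; "
            f"have {n_pre} before and {n_post} after"
        )
    pre_block = monthly[monthly.index < fire_month].iloc[-WINDOW_MONTHS:]
    post_block = monthly[monthly.index >= fire_month].iloc[:WINDOW_MONTHS]
    pre = _window_values(pre_block)
    post = _window_values(post_block)
    delta = {k: post[k] - pre[k] for k in pre}
    delta_pct, undefined = {}, []
    for k in pre:
        if pre[k] == 0.0:
            delta_pct[k] = float("nan")
            undefined.append(k)
        else:
            delta_pct[k] = 100.0 * delta[k] / pre[k]
    return WindowSummary(
        pre=pre, post=post, delta=delta, delta_pct=delta_pct,
        undefined_pct=tuple(undefined), fire_month=fire_month,
    )


def annual_records(monthly: pd.DataFrame, fire_date, n_years: int = 5,
                   side: str = "pre") -> pd.DataFrame:
    """Annual P, PET, SWE, Q and sigma2_Pm for 12-month blocks around a fire.

    Years are counted in consecutive 12-month blocks backwards (``pre``)
    or forwards (``post``) from the fire month, so each "year" is a full
    block regardless of calendar alignment. Used to fit climate
    elasticity models on pre-fire data.
    """
    if not isinstance(monthly.index, pd.PeriodIndex):
        raise TypeError("monthly record must have a PeriodIndex (freq='M')")
    fire_month = pd.Period(fire_date, freq="M")
    if side == "pre":
        block = monthly[monthly.index < fire_month].iloc[-12 * n_years:]
    elif side == "post":
        block = monthly[monthly.index >= fire_month].iloc[:12 * n_years]
    else:
        raise ValueError("side must be 'pre' or 'post'")
    if len(block) < 12 * n_years:
        raise ValueError(
            f"need {12 * n_years} months on the {side} side, have {len(block)}"
        )
    rows = []
    for i in range(n_years):
        yr = block.iloc[12 * i: 12 * (i + 1)]
        row = {}
        for col in ("P", "PET", "Q"):
            if col in yr:
                row[col] = float(yr[col].sum())
        if "SWE" in yr:
            row["SWE"] = float(yr["SWE"].mean())
        if "P" in yr:
            row["sigma2_Pm"] = float(yr["P"].var(ddof=1))
        rows.append(row)
    return pd.DataFrame(rows)
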