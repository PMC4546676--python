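"""Forest-harvest and climate-change regime transformations.

A scenario turns a baseline daily regime series into an altered series by
adding temperature offsets and multiplying flows:

* **Forest harvest** (pulsed, one event per entry in ``harvest_years``,
  default years 1 and 41 of the analysis horizon — a 40-year rotation):
  daily temperature +0.37 °C for five post-harvest years, then a linear
  decline of 0.037 °C/yr that restores baseline in post-harvest year 16;
  summer (Jul–Sep) flows +45 % for five years, ramping linearly back to
  baseline exactly at post-harvest year 20; storm-day water yield +20 % on
  days whose baseline flow exceeds the annual mean by more than 2 SD, while
  harvest flow effects are active.
* **Climate change** (press): temperature +0.06 °C per analysis year
  (3.78 °C at year 63); fall (Oct–Dec) flows −0.25 percentage points per
  year and winter (Jan–Mar) flows −0.49 points per year (−15.75 % and
  −30.87 % at year 63).  Declines accumulate additively, not compounding.
* **Combined**: harvest transforms first, then climate transforms.

Offsets add and multipliers multiply, and the storm-day mask is always
computed on the *baseline* flow series, so for every day
``combined_temp = baseline + harvest_offset + climate_offset`` and
``combined_flow = baseline × harvest_multipliers × climate_multiplier``.
Turbidity passes through untouched.  The component mask restricts a scenario
to its temperature or flow alterations only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .environment import DAYS_PER_YEAR

HARVEST_SUMMER_MONTHS = frozenset({7, 8, 9})
CLIMATE_FALL_MONTHS = frozenset({10, 11, 12})
CLIMATE_WINTER_MONTHS = frozenset({1, 2, 3})

SCENARIO_KINDS = ("baseline", "harvest", "climate", "combined")


@dataclass(frozen=True)
class ScenarioSpec:
    """Declarative description of one scenario and its component mask."""

    kind: str = "baseline"
    temperature: bool = True  # apply the scenario's temperature alterations
    flow: bool = True  # apply the scenario's flow alterations
    harvest_years: tuple[int, ...] = (1, 41)  # 1-based analysis years
    harvest_temp_pulse: float = 0.37  # °C
    harvest_temp_recovery_rate: float = 0.037  # °C/yr
    harvest_plateau_years: int = 5
    harvest_temp_recovery_span: int = 10  # yr of decline after the plateau
    storm_multiplier: float = 1.20
    storm_threshold_sd: float = 2.0
    summer_flow_boost: float = 0.45  # fraction above baseline
    summer_flow_recovery_year: int = 20  # post-harvest year at baseline
    climate_warming_rate: float = 0.06  # °C/yr
    fall_flow_decline: float = 0.25  # percentage points per year, Oct–Dec
    winter_flow_decline: float = 0.49  # percentage points per year, Jan–Mar

    def __post_init__(self):
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.kind != "baseline" and not (self.temperature or self.flow):
            raise ValueError("component mask must select temperature, flow, or both")
        for name in (
            "harvest_temp_pulse", "harvest_temp_recovery_rate",
            "summer_flow_boost", "climate_warming_rate",
            "fall_flow_decline", "winter_flow_decline",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(h < 1 for h in self.harvest_years):
            raise ValueError("harvest years are 1-based analysis years")

    def with_components(self, temperature: bool, flow: bool) -> "ScenarioSpec":
        return replace(self, temperature=temperature, flow=flow)


BASELINE = ScenarioSpec(kind="baseline")
HARVEST = ScenarioSpec(kind="harvest")
CLIMATE = ScenarioSpec(kind="climate")
COMBINED = ScenarioSpec(kind="combined")


def harvest_temperature_offset(
    years_since_harvest: int, spec: ScenarioSpec = HARVEST
) -> float:
    """Temperature offset (°C) by 1-based post-harvest year.

    Plateau at the pulse for the first five years, then a linear decline of
    ``harvest_temp_recovery_rate`` per year (first decremented value in
    post-harvest year 7) so the last elevated year is year 15 and baseline is
    restored exactly in year 16, matching the stated 15 elevated years.
    """
    y = int(years_since_harvest)
    if y < 1:
        raise ValueError("years_since_harvest is 1-based")
    p = spec.harvest_plateau_years
    s = spec.harvest_temp_recovery_span
    if y <= p:
        return spec.harvest_temp_pulse
    if y <= p + s:
        return max(spec.harvest_temp_pulse
                   - spec.harvest_temp_recovery_rate * (y - p - 1), 0.0)
    return 0.0


def harvest_summer_flow_multiplier(
    years_since_harvest: int, spec: ScenarioSpec = HARVEST
) -> float:
    """Jul–Sep flow multiplier by 1-based post-harvest year.

    1.45 for five years, then a linear ramp that reaches 1.0 exactly at
    post-harvest year 20 (the stated recovery year; a constant −2.25 %/yr
    would leave +11.25 % at year 20, so the ramp honors the recovery year).
    """
    y = int(years_since_harvest)
    if y < 1:
        raise ValueError("years_since_harvest is 1-based")
    p = spec.harvest_plateau_years
    r = spec.summer_flow_recovery_year
    if y <= p:
        return 1.0 + spec.summer_flow_boost
    if y < r:
        return 1.0 + spec.summer_flow_boost * (r - y) / (r - p)
    return 1.0


def harvest_storm_active(years_since_harvest: int, spec: ScenarioSpec = HARVEST) -> bool:
    """Whether the +20 % storm-day yield increase applies in this post-harvest year.

    Active while harvest flow alterations persist, i.e. until the summer-flow
    ramp reaches baseline (post-harvest years 1–19 by default).
    """
    y = int(years_since_harvest)
    if y < 1:
        raise ValueError("years_since_harvest is 1-based")
    return y < spec.summer_flow_recovery_year


def climate_temperature_offset(analysis_year: int, spec: ScenarioSpec = CLIMATE) -> float:
    """Cumulative warming (°C) for a 1-based analysis year; 0 for year 0 (guard)."""
    y = int(analysis_year)
    if y < 0:
        raise ValueError("analysis_year must be >= 0")
    return spec.climate_warming_rate * y


def climate_flow_multiplier(
    analysis_year: int, month: int, spec: ScenarioSpec = CLIMATE
) -> float:
    """Seasonal flow multiplier under the climate scenario (additive decline)."""
    y = int(analysis_year)
    if y < 1:
        raise ValueError("analysis_year is 1-based")
    if month in CLIMATE_FALL_MONTHS:
        return 1.0 - spec.fall_flow_decline / 100.0 * y
    if month in CLIMATE_WINTER_MONTHS:
        return 1.0 - spec.winter_flow_decline / 100.0 * y
    return 1.0


def storm_day_mask(
    flow: np.ndarray, threshold_sd: float = 2.0, days_per_year: int = DAYS_PER_YEAR
) -> np.ndarray:
    """True where flow > annual mean + threshold_sd × annual SD (per year block).

    Mean and SD (sample SD, ddof=1) are computed within each consecutive
    ``days_per_year`` block of the series.
    """
    flow = np.asarray(flow, dtype=float)
    if flow.size == 0:
        raise ValueError("flow series is empty")
    mask = np.zeros(flow.size, dtype=bool)
    for start in range(0, flow.size, days_per_year):
        block = flow[start : start + days_per_year]
        mu = block.mean()
        sd = block.std(ddof=1) if block.size > 1 else 0.0
        mask[start : start + block.size] = block > mu + threshold_sd * sd
    return mask


def _analysis_years(n_days: int, init_years: int) -> np.ndarray:
    """1-based analysis year per day; ≤ 0 during the discarded spin-up years."""
    return np.arange(n_days) // DAYS_PER_YEAR + 1 - init_years


def apply_scenario(
    baseline: pd.DataFrame, spec: ScenarioSpec, init_years: int = 0
) -> pd.DataFrame:
    """Transform a baseline regime series according to a scenario spec.

    ``init_years`` leading water years (model spin-up, discarded from the
    analysis) are left untouched; scenario clocks start at the first analysis
    year.  Days outside every modified window are bit-identical to baseline.
    """
    n = len(baseline)
    if n == 0:
        raise ValueError("baseline series is empty")
    years = _analysis_years(n, init_years)
    if spec.kind != "baseline" and spec.harvest_years and spec.kind in (
        "harvest", "combined"
    ):
        horizon = years.max()
        if any(h > horizon for h in spec.harvest_years):
            raise ValueError("harvest year beyond the analysis horizon")

    out = baseline.copy()
    if spec.kind == "baseline":
        return out

    months = pd.to_datetime(out["date"]).dt.month.to_numpy()
    temp = out["temp_c"].to_numpy(float).copy()
    flow0 = out["flow_m3s"].to_numpy(float)
    flow = flow0.copy()

    do_harvest = spec.kind in ("harvest", "combined")
    do_climate = spec.kind in ("climate", "combined")
    active = years >= 1

    if do_harvest:
        if spec.temperature:
            offs = np.zeros(n)
            for h in spec.harvest_years:
                yss = years - h + 1
                valid = active & (yss >= 1)
                for y in np.unique(yss[valid]):
                    offs[valid & (yss == y)] += harvest_temperature_offset(y, spec)
            temp = temp + offs
        if spec.flow:
            mult = np.ones(n)
            # storm mask on the baseline series, per analysis-year block
            smask = storm_day_mask(flow0, spec.storm_threshold_sd)
            is_summer = np.isin(months, list(HARVEST_SUMMER_MONTHS))
            for h in spec.harvest_years:
                yss = years - h + 1
                valid = active & (yss >= 1)
                for y in np.unique(yss[valid]):
                    sel = valid & (yss == y)
                    m = harvest_summer_flow_multiplier(y, spec)
                    mult[sel & is_summer] *= m
                    if harvest_storm_active(y, spec):
                        mult[sel & smask] *= spec.storm_multiplier
            flow = flow * mult

    if do_climate:
        if spec.temperature:
            temp = temp + np.where(
                active, spec.climate_warming_rate * np.maximum(years, 0), 0.0
            )
        if spec.flow:
            mult = np.ones(n)
            is_fall = np.isin(months, list(CLIMATE_FALL_MONTHS))
            is_winter = np.isin(months, list(CLIMATE_WINTER_MONTHS))
            yv = np.maximum(years, 0)
            mult = np.where(
                active & is_fall, 1.0 - spec.fall_flow_decline / 100.0 * yv, mult
            )
            mult = np.where(
                active & is_winter, 1.0 - spec.winter_flow_decline / 100.0 * yv, mult
            )
            flow = flow * mult

    out["temp_c"] = temp
    out["flow_m3s"] = flow
    return out
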