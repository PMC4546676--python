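"""Reduce replicate simulation output to population response variables.

The study's response variables: seasonal (summer = July–August, winter =
January–February) biomass, growth and survival per age class (0, 1, 2, 3+;
no age 0 in winter because ages increment on January 1), per-year median
fry-emergence day of year, and percent change of a scenario median against
baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

SEASON_MONTHS = {"summer": (7, 8), "winter": (1, 2)}
AGE_CLASSES = (0, 1, 2, 3)  # 3 pools ages >= 3
DAYS_PER_YEAR = 365


def age_class_of(age) -> int:
    return min(int(age), 3)


@dataclass
class ResponseTable:
    """Tidy per-(stream, scenario, replicate, year, season, age-class) summaries
    plus per-year median emergence DOY."""

    responses: pd.DataFrame  # ... biomass_g, growth_cm_per_month, survival
    emergence: pd.DataFrame  # stream, scenario, replicate, year, emergence_doy

    def replicate_mean_responses(self) -> pd.DataFrame:
        """Mean over replicates for every (stream, scenario, year, season,
        age-class) cell, recording the replicate count."""
        g = self.responses.groupby(
            ["stream", "scenario", "year", "season", "age_class"], sort=True
        )
        out = g.agg(
            biomass_g=("biomass_g", "mean"),
            growth_cm_per_month=("growth_cm_per_month", "mean"),
            survival=("survival", "mean"),
            n_replicates=("replicate", "nunique"),
        ).reset_index()
        return out


def annotate_years(snapshots: pd.DataFrame, init_years: int = 0) -> pd.DataFrame:
    """Attach the 1-based analysis year (water-year block of day_index minus
    the spin-up years); rows in spin-up years get year <= 0."""
    out = snapshots.copy()
    out["year"] = out["day_index"] // DAYS_PER_YEAR + 1 - init_years
    return out


def seasonal_summary(
    snapshots: pd.DataFrame, season: str, age_class: int
) -> pd.DataFrame:
    """Per-year biomass, growth and survival for one season and age class.

    Snapshots are the 30-day-cadence population dumps of one replicate with a
    ``year`` column.  Biomass is the mean over in-season snapshots of summed
    weights; growth is the mean per-individual fork-length change of fish
    present at consecutive in-season snapshots, scaled to cm per 30 days;
    survival is the fraction of the class present at the first in-season
    snapshot still alive at the last.  Seasons with no snapshots yield NaN.
    """
    if season not in SEASON_MONTHS:
        raise ValueError(f"season must be one of {sorted(SEASON_MONTHS)}")
    months = SEASON_MONTHS[season]
    snaps = snapshots[snapshots["year"] >= 1]
    dates = pd.to_datetime(snaps["date"])
    in_season = dates.dt.month.isin(months)
    rows = []
    for year, sub in snaps[in_season].groupby("year", sort=True):
        sub = sub.copy()
        klass = np.minimum(sub["age"], 3) == age_class
        sub_k = sub[klass]
        times = sorted(sub["day_index"].unique())
        if not times:
            continue
        biomass = (
            sub_k.groupby("day_index")["weight"].sum()
            .reindex(times, fill_value=0.0).mean()
        )
        # growth: survivors present at consecutive snapshot pairs
        deltas = []
        for t0, t1 in zip(times[:-1], times[1:]):
            a = sub_k[sub_k["day_index"] == t0].set_index("fish_id")["length"]
            b = sub[sub["day_index"] == t1].set_index("fish_id")["length"]
            common = a.index.intersection(b.index)
            if len(common):
                per_day = (b[common] - a[common]) / (t1 - t0)
                deltas.extend((per_day * 30.0).tolist())
        growth = float(np.mean(deltas)) if deltas else math.nan
        # survival: class members at season start alive at season end
        start_ids = set(sub_k[sub_k["day_index"] == times[0]]["fish_id"])
        if start_ids:
            end_ids = set(sub[sub["day_index"] == times[-1]]["fish_id"])
            survival = len(start_ids & end_ids) / len(start_ids)
        else:
            survival = math.nan
        rows.append((int(year), season, age_class, float(biomass), growth,
                     survival))
    return pd.DataFrame(
        rows,
        columns=["year", "season", "age_class", "biomass_g",
                 "growth_cm_per_month", "survival"],
    )


def median_emergence_doy(emergence_doys) -> float:
    """Smallest DOY by which at least half of the year's fry have emerged.

    ``emergence_doys`` is the per-fish emergence day-of-year list for one
    year (repeats allowed).  Returns NaN when no fry emerged that year.
    """
    doys = np.sort(np.asarray(list(emergence_doys), dtype=float))
    n = doys.size
    if n == 0:
        return math.nan
    half = n / 2.0
    cum = np.arange(1, n + 1)
    return float(doys[np.argmax(cum >= half)])


def yearly_emergence(emergence: pd.DataFrame, init_years: int = 0) -> pd.DataFrame:
    """Per-analysis-year median emergence DOY from an emergence event log
    (columns date, day_index, count)."""
    if emergence.empty:
        return pd.DataFrame(columns=["year", "emergence_doy"])
    ev = emergence.copy()
    ev["year"] = ev["day_index"] // DAYS_PER_YEAR + 1 - init_years
    ev["doy"] = pd.to_datetime(ev["date"]).dt.dayofyear
    rows = []
    for year, sub in ev[ev["year"] >= 1].groupby("year", sort=True):
        doys = np.repeat(sub["doy"].to_numpy(), sub["count"].to_numpy())
        rows.append((int(year), median_emergence_doy(doys)))
    return pd.DataFrame(rows, columns=["year", "emergence_doy"])


def percent_change(median_scenario: float, median_baseline: float) -> float:
    """[(median scenario − median baseline)/median baseline] × 100."""
    if median_baseline == 0:
        raise ZeroDivisionError("baseline median is zero; percent change undefined")
    return (median_scenario - median_baseline) / median_baseline * 100.0


def replicate_mean(values) -> float:
    """Arithmetic mean over replicate values."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("need at least one replicate")
    return float(values.mean())


def summarize_replicate(
    snapshots: pd.DataFrame,
    emergence: pd.DataFrame,
    init_years: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All seasonal summaries plus yearly emergence for one replicate.

    Winter tables never contain age-0 rows (no age 0 exists in winter).
    """
    snaps = annotate_years(snapshots, init_years)
    parts = []
    for season in SEASON_MONTHS:
        for ac in AGE_CLASSES:
            if season == "winter" and ac == 0:
                continue
            parts.append(seasonal_summary(snaps, season, ac))
    responses = (
        pd.concat(parts, ignore_index=True)
        if parts
        else pd.DataFrame()
    )
    emerg = yearly_emergence(emergence, init_years)
    return responses, emerg
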