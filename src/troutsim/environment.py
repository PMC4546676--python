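"""Synthetic daily environmental regimes and reach geometries.

Headwater streams of the Oregon Coast Range have rain-dominated hydrographs:
flashy winter storm flows (October–March), a spring recession, and an extended
late-summer low-flow period, with moderate year-round temperatures (roughly
6–12 °C).  This module generates daily regime series (flow, temperature,
turbidity) with that structure, builds reach geometries made of rectangular
microhabitat cells, and assembles multi-decade input series by resampling
observed water years — the study design the simulator consumes.

Regime series are tidy :class:`pandas.DataFrame` objects with columns
``date, flow_m3s, temp_c, turbidity_ntu``, one row per day, no gaps.
Generated years are 365-day water years (Oct 1 – Sep 30, leap days dropped)
so that the storm season never straddles a resampling boundary.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import RegimeFormatError

REGIME_COLUMNS = ["date", "flow_m3s", "temp_c", "turbidity_ntu"]
CELL_COLUMNS = [
    "cell_id",
    "area_m2",
    "ref_depth_m",
    "ref_velocity_ms",
    "depth_exponent",
    "velocity_exponent",
    "shelter_fraction",
    "gravel_fraction",
    "dist_cover_m",
]

DAYS_PER_YEAR = 365
#: nominal first day of the first generated water year
DEFAULT_START = "2006-10-01"


@dataclass(frozen=True)
class StreamParams:
    """Generator parameters describing one stream's regime and geometry.

    The temperature model is a seasonal sinusoid between ``temp_winter_min``
    and ``temp_summer_max`` (trough in late January, peak in early August)
    with Gaussian daily noise.  Flow is a smooth seasonal baseflow curve
    (winter baseflow ``winter_baseflow_ratio`` times the summer level) with
    Poisson-arriving lognormal storm spikes in October–March that decay over
    ~3 days; ``storm_amplitude`` scales all storm/noise structure and 0 turns
    it off exactly.  Turbidity is coupled to the flow anomaly above baseflow.
    """

    name: str = "default"
    summer_flow: float = 0.08  # m³/s, mean late-summer baseflow; reference flow
    winter_flow_cv: float = 1.0  # coefficient of variation of winter daily flow
    temp_winter_min: float = 6.0  # °C
    temp_summer_max: float = 12.0  # °C
    turbidity_coupling: float = 20.0  # NTU per (m³/s) of flow anomaly
    reach_length: float = 230.0  # m, target; generated within 210–250
    n_cells: int = 33  # target; generated within 31–35
    base_pool_depth: float = 0.40  # m, reference pool depth at summer flow
    # secondary knobs (defaults shared by all presets)
    winter_baseflow_ratio: float = 6.0  # winter/summer baseflow multiplier
    storm_rate: float = 12.0  # expected storms per Oct–Mar season
    storm_amplitude: float = 1.0  # scales storm spikes and flow noise; 0 = smooth
    summer_noise_cv: float = 0.05  # extra lognormal noise sd (Jun–Sep)
    temp_noise_sd: float = 0.3  # °C
    gravel_cell_fraction: float = 0.2  # share of cells carrying spawning gravel

    def __post_init__(self):
        if self.temp_winter_min >= self.temp_summer_max:
            raise ValueError("temp_winter_min must be < temp_summer_max")
        for name in ("summer_flow", "reach_length", "n_cells", "base_pool_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


#: Presets mirroring the qualitative contrasts among the four study streams:
#: "gus" has the most variable winter flow and the deepest pools, "pothole"
#: the strongest turbidity–flow coupling, "rock" the largest and most variable
#: summer flows, "um" is the coldest and smallest.  Directions only — these
#: are synthetic streams, not field data.
PRESETS: dict[str, StreamParams] = {
    "gus": StreamParams(
        name="gus", summer_flow=0.08, winter_flow_cv=1.4, base_pool_depth=0.50,
        turbidity_coupling=15.0,
    ),
    "pothole": StreamParams(
        name="pothole", summer_flow=0.06, winter_flow_cv=0.9, base_pool_depth=0.32,
        turbidity_coupling=45.0,
    ),
    "rock": StreamParams(
        name="rock", summer_flow=0.11, winter_flow_cv=1.1, base_pool_depth=0.38,
        turbidity_coupling=20.0, summer_noise_cv=0.20, reach_length=245.0,
    ),
    "um": StreamParams(
        name="um", summer_flow=0.045, winter_flow_cv=1.0, base_pool_depth=0.28,
        temp_winter_min=5.0, temp_summer_max=10.5, turbidity_coupling=20.0,
        reach_length=215.0, n_cells=32,
    ),
}


def get_preset(name: str) -> StreamParams:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown stream preset {name!r}; choose from {sorted(PRESETS)}"
        ) from None


@dataclass(frozen=True)
class Cell:
    """One rectangular microhabitat cell.

    Depth and velocity at arbitrary flow follow power-law hydraulic ratings
    anchored at (``ref_depth``, ``ref_velocity``) for the reach reference flow.
    """

    cell_id: int
    area: float  # m²
    ref_depth: float  # m at reference flow
    ref_velocity: float  # m/s at reference flow
    depth_exponent: float
    velocity_exponent: float
    shelter_fraction: float  # 0–1, velocity shelter for drift feeding
    gravel_fraction: float  # 0–1, spawning gravel
    dist_cover: float  # m to hiding cover

    def __post_init__(self):
        if self.area <= 0:
            raise ValueError("cell area must be positive")
        for name in ("shelter_fraction", "gravel_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.ref_depth < 0 or self.ref_velocity < 0:
            raise ValueError("reference depth/velocity must be non-negative")


@dataclass(frozen=True)
class ReachGeometry:
    """An ordered set of cells plus reach length and the rating reference flow."""

    cells: tuple[Cell, ...]
    reach_length: float  # m
    ref_flow: float  # m³/s

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (
                c.cell_id, c.area, c.ref_depth, c.ref_velocity,
                c.depth_exponent, c.velocity_exponent,
                c.shelter_fraction, c.gravel_fraction, c.dist_cover,
            )
            for c in self.cells
        ]
        df = pd.DataFrame(rows, columns=CELL_COLUMNS)
        return df

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, reach_length: float, ref_flow: float
    ) -> "ReachGeometry":
        missing = [c for c in CELL_COLUMNS if c not in df.columns]
        if missing:
            raise RegimeFormatError(f"reach table missing columns {missing}")
        cells = tuple(
            Cell(
                cell_id=int(r.cell_id), area=float(r.area_m2),
                ref_depth=float(r.ref_depth_m), ref_velocity=float(r.ref_velocity_ms),
                depth_exponent=float(r.depth_exponent),
                velocity_exponent=float(r.velocity_exponent),
                shelter_fraction=float(r.shelter_fraction),
                gravel_fraction=float(r.gravel_fraction),
                dist_cover=float(r.dist_cover_m),
            )
            for r in df.itertuples()
        )
        return cls(cells=cells, reach_length=reach_length, ref_flow=ref_flow)


def _water_year_dates(n_years: int, start: str = DEFAULT_START) -> pd.DatetimeIndex:
    """Consecutive calendar dates covering n 365-day water years, Feb 29 dropped."""
    start_ts = pd.Timestamp(start)
    n = n_years * DAYS_PER_YEAR
    # generate with slack for leap days, then drop Feb 29 and truncate
    raw = pd.date_range(start_ts, periods=n + n_years // 4 + 2, freq="D")
    keep = raw[~((raw.month == 2) & (raw.day == 29))]
    return keep[:n]


def _seasonal_baseflow(params: StreamParams, day_of_wy: np.ndarray) -> np.ndarray:
    """Smooth seasonal baseflow (m³/s) indexed by day of water year (0 = Oct 1)."""
    # winter weight peaks in early January (day ~95), with a wide flat
    # late-summer trough; exponent skews the curve toward extended low flow
    w = 0.5 * (1.0 + np.cos(2.0 * np.pi * (day_of_wy - 95.0) / DAYS_PER_YEAR))
    w = w ** 1.6
    return params.summer_flow * np.exp(np.log(params.winter_baseflow_ratio) * w)


def _seasonal_temperature(params: StreamParams, cal_doy: np.ndarray) -> np.ndarray:
    """Seasonal sinusoid between winter min and summer max, peak ~Aug 1."""
    mid = 0.5 * (params.temp_winter_min + params.temp_summer_max)
    amp = 0.5 * (params.temp_summer_max - params.temp_winter_min)
    return mid + amp * np.cos(2.0 * np.pi * (cal_doy - 213.0) / 365.25)


def generate_daily_regime(
    params: StreamParams, n_years: int, seed: int, start: str = DEFAULT_START
) -> pd.DataFrame:
    """Generate ``n_years`` 365-day water years of daily flow/temperature/turbidity.

    Flow is the smooth seasonal baseflow modulated (in log space) by
    Poisson-arriving storm pulses with ~3-day exponential recessions plus
    small daily noise; both are scaled by ``params.storm_amplitude`` so that
    amplitude 0 returns the baseflow curve exactly.  Turbidity is
    ``turbidity_coupling`` times the positive flow anomaly above baseflow.
    Deterministic for a fixed seed.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    rng = np.random.default_rng(seed)
    dates = _water_year_dates(n_years, start)
    n = len(dates)
    day_of_wy = np.arange(n) % DAYS_PER_YEAR
    cal_doy = dates.dayofyear.to_numpy().astype(float)

    temp = _seasonal_temperature(params, cal_doy) + rng.normal(
        0.0, params.temp_noise_sd, n
    )

    base = _seasonal_baseflow(params, day_of_wy)

    # storm pulses: Poisson arrivals within Oct–Mar (day-of-WY < 182)
    log_pulse = np.zeros(n)
    # pulse magnitude tuned so winter daily-flow CV tracks winter_flow_cv
    sigma_peak = 0.45 * params.winter_flow_cv
    mu_peak = np.log(max(params.winter_flow_cv, 0.05) * 2.0)
    p_storm = params.storm_rate / 182.0
    storm_draws = rng.random(n)
    peak_draws = rng.normal(mu_peak, sigma_peak, n)
    for t in np.nonzero((day_of_wy < 182) & (storm_draws < p_storm))[0]:
        peak = np.exp(peak_draws[t])  # multiplicative peak height - 1
        for lag in range(4):
            if t + lag < n:
                log_pulse[t + lag] += np.log1p(peak * np.exp(-lag / 1.1))

    # small daily noise, larger in summer for streams with variable low flow
    summer = (dates.month >= 6) & (dates.month <= 9)
    noise_sd = np.where(summer, params.summer_noise_cv, 0.05)
    log_noise = rng.normal(0.0, 1.0, n) * noise_sd

    flow = base * np.exp(params.storm_amplitude * (log_pulse + log_noise))

    turbidity = np.maximum(params.turbidity_coupling * (flow - base), 0.0)

    return pd.DataFrame(
        {
            "date": dates,
            "flow_m3s": flow,
            "temp_c": temp,
            "turbidity_ntu": turbidity,
        }
    )


def generate_reach(params: StreamParams, seed: int) -> ReachGeometry:
    """Generate a reach of 31–35 rectangular cells totalling 210–250 m.

    Cells alternate pool-like (deep, slow) and riffle-like (shallow, fast)
    habitat; a minority (``gravel_cell_fraction``) carry spawning gravel.
    Reference hydraulics are anchored at the stream's summer baseflow.
    """
    rng = np.random.default_rng(seed)
    n_cells = int(np.clip(params.n_cells + rng.integers(-2, 3), 31, 35))
    length = float(np.clip(params.reach_length * rng.uniform(0.96, 1.04), 210.0, 250.0))
    cell_len = length / n_cells
    qref = params.summer_flow

    is_pool = (np.arange(n_cells) % 2 == 0)
    depth = np.where(
        is_pool,
        params.base_pool_depth * rng.uniform(0.7, 1.3, n_cells),
        params.base_pool_depth * rng.uniform(0.25, 0.6, n_cells),
    )
    width = np.clip(
        qref / (np.where(is_pool, 0.12, 0.35) * depth) * rng.uniform(0.8, 1.2, n_cells),
        0.8, 6.0,
    )
    velocity = qref / (depth * width)  # continuity at reference flow

    n_gravel = max(1, int(round(params.gravel_cell_fraction * n_cells)))
    gravel_cells = rng.choice(n_cells, size=n_gravel, replace=False)
    gravel = np.zeros(n_cells)
    if params.gravel_cell_fraction > 0:
        gravel[gravel_cells] = rng.uniform(0.1, 0.4, n_gravel)

    cells = tuple(
        Cell(
            cell_id=i,
            area=float(cell_len * width[i]),
            ref_depth=float(depth[i]),
            ref_velocity=float(velocity[i]),
            depth_exponent=float(rng.uniform(0.35, 0.45)),
            velocity_exponent=float(rng.uniform(0.35, 0.45)),
            shelter_fraction=float(rng.uniform(0.0, 0.4)),
            gravel_fraction=float(gravel[i]),
            dist_cover=float(np.clip(rng.exponential(3.0), 0.5, 15.0)),
        )
        for i in range(n_cells)
    )
    return ReachGeometry(cells=cells, reach_length=length, ref_flow=qref)


def resample_year_sequence(
    observed_year_labels: Sequence, horizon_years: int, seed: int
) -> list:
    """Uniformly resample observed year labels with replacement for the horizon."""
    labels = list(observed_year_labels)
    if not labels:
        raise ValueError("observed_year_labels must be non-empty")
    if horizon_years < 1:
        raise ValueError("horizon_years must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(labels), size=horizon_years)
    return [labels[i] for i in idx]


def assemble_input_series(
    regimes_by_year: Mapping, year_sequence: Sequence, start: str = DEFAULT_START
) -> pd.DataFrame:
    """Concatenate whole-year regimes in sequence order with consecutive dates.

    Dates of the assembled series are rewritten to run consecutively from
    ``start`` (Feb 29 skipped, matching 365-day year blocks).
    """
    parts = []
    for label in year_sequence:
        if label not in regimes_by_year:
            raise KeyError(f"no regime for year label {label!r}")
        parts.append(regimes_by_year[label])
    out = pd.concat(parts, ignore_index=True)
    n_years = len(out) // DAYS_PER_YEAR
    if len(out) % DAYS_PER_YEAR:
        n_years += 1
    dates = _water_year_dates(n_years, start)[: len(out)]
    out = out.copy()
    out["date"] = dates
    return out


def split_years(series: pd.DataFrame) -> dict[int, pd.DataFrame]:
    """Split a generated series into its 365-day water-year blocks, keyed 0..n-1."""
    n_years = len(series) // DAYS_PER_YEAR
    return {
        y: series.iloc[y * DAYS_PER_YEAR : (y + 1) * DAYS_PER_YEAR].reset_index(
            drop=True
        )
        for y in range(n_years)
    }


def write_regime_csv(series: pd.DataFrame, path) -> None:
    out = series.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, columns=REGIME_COLUMNS)


def read_regime_csv(path) -> pd.DataFrame:
    """Read and validate a regime CSV: contiguous dates, flow > 0, turbidity ≥ 0."""
    df = pd.read_csv(path)
    missing = [c for c in REGIME_COLUMNS if c not in df.columns]
    if missing:
        raise RegimeFormatError(f"regime file missing columns {missing}")
    try:
        dates = pd.to_datetime(df["date"], format="%Y-%m-%d")
    except (ValueError, TypeError) as exc:
        raise RegimeFormatError(f"unparseable date: {exc}") from exc
    deltas = dates.diff().dt.days.to_numpy()[1:]
    # a two-day step across Feb 29 is the 365-day-year convention, not a gap
    prev = dates.iloc[:-1]
    leap_skip = (
        (deltas == 2) & (prev.dt.month == 2).to_numpy()
        & (prev.dt.day == 28).to_numpy()
    )
    bad = np.nonzero((deltas != 1) & ~leap_skip)[0]
    if bad.size:
        raise RegimeFormatError("gap or disorder in dates", row=int(bad[0]) + 1)
    flow = df["flow_m3s"].to_numpy(float)
    nonpos = np.nonzero(~(flow > 0))[0]
    if nonpos.size:
        raise RegimeFormatError("non-positive flow", row=int(nonpos[0]))
    turb = df["turbidity_ntu"].to_numpy(float)
    neg = np.nonzero(turb < 0)[0]
    if neg.size:
        raise RegimeFormatError("negative turbidity", row=int(neg[0]))
    out = df[REGIME_COLUMNS].copy()
    out["date"] = dates
    return out


def write_reach_csv(reach: ReachGeometry, path) -> None:
    df = reach.to_frame()
    df.insert(0, "reach_length_m", reach.reach_length)
    df.insert(1, "ref_flow_m3s", reach.ref_flow)
    df.to_csv(path, index=False)


def read_reach_csv(path) -> ReachGeometry:
    df = pd.read_csv(path)
    for col in ("reach_length_m", "ref_flow_m3s"):
        if col not in df.columns:
            raise RegimeFormatError(f"reach file missing column {col!r}")
    return ReachGeometry.from_frame(
        df, reach_length=float(df["reach_length_m"].iloc[0]),
        ref_flow=float(df["ref_flow_m3s"].iloc[0]),
    )
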