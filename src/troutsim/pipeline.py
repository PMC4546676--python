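"""End-to-end experiment orchestration.

One config drives the whole design: per stream, generate (or load) five
observed water years of regimes and a reach; resample those years uniformly
into a 67-year series (the ordering is shared by every scenario of that
stream, so scenarios differ only by the regime transformation); apply each
scenario starting at analysis year 1 (after 4 spin-up years, discarded);
run seeded replicates of the IBM; summarize responses; and compute the
scenario-comparison and trend statistics over the 63 analysis years.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import environment as env
from . import responses as resp
from . import stats as st
from .errors import ConfigError
from .ibm import IbmParams, run_simulation
from .scenario import ScenarioSpec, apply_scenario

SCENARIO_NAMES = ("baseline", "harvest", "climate", "combined")


@dataclass
class RunConfig:
    """Configuration of one experiment."""

    streams: tuple[str, ...] = ("gus",)
    scenarios: tuple[str, ...] = ("baseline",)
    horizon_years: int = 67
    init_years: int = 4  # spin-up years discarded from the analysis
    replicates: int = 5
    output_every: int = 30  # days between population snapshots
    harvest_years: tuple[int, ...] = (1, 41)
    separate_effects: bool = False  # expand scenarios into T-only/Q-only/T+Q
    master_seed: int = 1
    n_observed_years: int = 5
    outdir: str | None = None
    ibm: dict = field(default_factory=dict)  # IbmParams field overrides

    @property
    def analysis_years(self) -> int:
        return self.horizon_years - self.init_years

    def validate(self) -> None:
        problems = []
        if self.replicates < 1:
            problems.append("replicates: must be >= 1")
        if self.horizon_years <= self.init_years:
            problems.append("horizon_years: must exceed init_years")
        if self.output_every < 1:
            problems.append("output_every: must be >= 1")
        if self.n_observed_years < 1:
            problems.append("n_observed_years: must be >= 1")
        for s in self.streams:
            if s not in env.PRESETS and not Path(str(s)).is_dir():
                problems.append(
                    f"streams.{s}: neither a preset nor a directory with "
                    "regime.csv and reach.csv"
                )
        unknown_ibm = set(self.ibm) - set(IbmParams.__dataclass_fields__)
        if unknown_ibm:
            problems.extend(f"ibm.{k}: unknown parameter"
                            for k in sorted(unknown_ibm))
        for s in self.scenarios:
            if s not in SCENARIO_NAMES:
                problems.append(
                    f"scenarios.{s}: must be one of {SCENARIO_NAMES}"
                )
        if any(h < 1 or h > self.analysis_years for h in self.harvest_years):
            problems.append("harvest_years: outside the analysis horizon")
        if problems:
            raise ConfigError("; ".join(problems))

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(
                "; ".join(f"{k}: unknown field" for k in sorted(unknown))
            )
        for key in ("streams", "scenarios", "harvest_years"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def derive_seed(master_seed: int, *key) -> int:
    """Stable sub-seed (< 2^31) from the master seed and a run key."""
    text = "|".join([str(master_seed), *map(str, key)])
    return zlib.crc32(text.encode()) & 0x7FFFFFFF


def build_scenario_suite(config: RunConfig) -> list[tuple[str, ScenarioSpec]]:
    """Expand configured scenario names into (label, spec) pairs.

    With ``separate_effects`` the harvest and climate scenarios are expanded
    into temperature-only (T), flow-only (Q) and combined-component (T+Q)
    variants; baseline and the combined scenario are never expanded.
    """
    suite: list[tuple[str, ScenarioSpec]] = []
    for name in config.scenarios:
        base = ScenarioSpec(kind=name, harvest_years=tuple(config.harvest_years))
        if name in ("harvest", "climate") and config.separate_effects:
            tag = "FH" if name == "harvest" else "CC"
            suite.append((f"{tag}-T", base.with_components(True, False)))
            suite.append((f"{tag}-Q", base.with_components(False, True)))
            suite.append((f"{tag}-T+Q", base))
        elif name == "baseline":
            suite.append(("baseline", base))
        else:
            label = {"harvest": "FH", "climate": "CC", "combined": "FH+CC"}[name]
            suite.append((label, base))
    return suite


TREND_WINDOWS = {"to_year_20": (1, 20), "year_20_on": (20, 63), "full": (1, 63)}
HARVEST_PERIODS = {"harvest_1": (1, 40), "harvest_2": (41, 63), "full": (1, 63)}


def summarize_periods(
    yearly: pd.DataFrame, value_col: str, windows: dict | None = None,
    analysis_years: int = 63,
) -> dict[str, st.TrendResult]:
    """Mann-Kendall trends of a per-year series over the analysis windows
    (default: years 1–20, 20–63, and the full span)."""
    if windows is None:
        windows = {
            k: (a, min(b, analysis_years)) for k, (a, b) in TREND_WINDOWS.items()
        }
    out = {}
    for name, (a, b) in windows.items():
        if a < 1 or b > analysis_years:
            raise ValueError(f"window {name} outside the analysis horizon")
        sub = yearly[(yearly["year"] >= a) & (yearly["year"] <= b)]
        vals = sub.sort_values("year")[value_col].dropna().to_numpy()
        if vals.size >= 4:
            out[name] = st.mann_kendall(vals)
    return out


@dataclass
class ExperimentResult:
    """Everything one experiment produced, plus provenance."""

    responses: resp.ResponseTable
    summer_total_biomass: pd.DataFrame  # stream, scenario, replicate, year, biomass_g
    statistics: dict[str, pd.DataFrame]
    provenance: dict


def _summer_total_biomass(snapshots: pd.DataFrame) -> pd.DataFrame:
    """Mean over July–August snapshots of total (all ages) biomass, per year."""
    snaps = snapshots[snapshots["year"] >= 1]
    dates = pd.to_datetime(snaps["date"])
    sub = snaps[dates.dt.month.isin((7, 8))]
    rows = []
    for year, s in sub.groupby("year", sort=True):
        per_snap = s.groupby("day_index")["weight"].sum()
        rows.append((int(year), float(per_snap.mean())))
    return pd.DataFrame(rows, columns=["year", "biomass_g"])


def run_experiment(config: RunConfig, ibm_params: IbmParams | None = None,
                   flow_scale: float = 1.0) -> ExperimentResult:
    """Run the full stream × scenario × replicate design.

    ``flow_scale`` uniformly rescales baseline flows before scenarios apply
    (used for baseflow sensitivity analyses).  Replicate seeds derive
    deterministically from (master seed, stream, scenario, replicate).
    """
    config.validate()
    params = ibm_params or IbmParams(**config.ibm)
    suite = build_scenario_suite(config)

    resp_rows = []
    emerg_rows = []
    biomass_rows = []
    replicate_seeds = {}

    for stream in config.streams:
        if stream in env.PRESETS:
            sp = env.get_preset(stream)
            env_seed = derive_seed(config.master_seed, "env", stream)
            observed = env.split_years(
                env.generate_daily_regime(sp, config.n_observed_years,
                                          seed=env_seed)
            )
            reach = env.generate_reach(sp, seed=derive_seed(
                config.master_seed, "reach", stream
            ))
        else:  # a directory holding observed regimes and the reach table
            folder = Path(str(stream))
            observed = env.split_years(env.read_regime_csv(folder / "regime.csv"))
            reach = env.read_reach_csv(folder / "reach.csv")
            if not observed:
                raise ConfigError(
                    f"streams.{stream}: regime.csv holds less than one "
                    "365-day water year"
                )
        seq = env.resample_year_sequence(
            sorted(observed), config.horizon_years,
            seed=derive_seed(config.master_seed, "seq", stream),
        )
        baseline = env.assemble_input_series(observed, seq)
        if flow_scale != 1.0:
            baseline = baseline.copy()
            baseline["flow_m3s"] = baseline["flow_m3s"] * flow_scale

        for label, spec in suite:
            series = apply_scenario(baseline, spec, init_years=config.init_years)
            for r in range(config.replicates):
                seed = derive_seed(config.master_seed, stream, label, r)
                replicate_seeds[f"{stream}/{label}/{r}"] = seed
                out = run_simulation(reach, series, params, seed,
                                     output_every=config.output_every)
                snaps = resp.annotate_years(out.snapshots, config.init_years)
                responses, emergence = resp.summarize_replicate(
                    out.snapshots, out.emergence, config.init_years
                )
                for df, rows in ((responses, resp_rows), (emergence, emerg_rows)):
                    df = df.copy()
                    df.insert(0, "stream", stream)
                    df.insert(1, "scenario", label)
                    df.insert(2, "replicate", r)
                    rows.append(df)
                biom = _summer_total_biomass(snaps)
                biom.insert(0, "stream", stream)
                biom.insert(1, "scenario", label)
                biom.insert(2, "replicate", r)
                biomass_rows.append(biom)

    responses = resp.ResponseTable(
        responses=pd.concat(resp_rows, ignore_index=True),
        emergence=pd.concat(emerg_rows, ignore_index=True),
    )
    biomass = pd.concat(biomass_rows, ignore_index=True)

    statistics = _compute_statistics(config, responses, biomass)
    provenance = {
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "replicate_seeds": replicate_seeds,
        "package": "troutsim",
    }
    return ExperimentResult(
        responses=responses, summer_total_biomass=biomass,
        statistics=statistics, provenance=provenance,
    )


def _compute_statistics(
    config: RunConfig, responses: resp.ResponseTable, biomass: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Scenario-vs-baseline statistics when more than one scenario ran.

    Per stream: Kruskal-Wallis across scenarios on yearly replicate-mean
    seasonal responses (pairwise rank comparisons when significant);
    Wilcoxon signed-rank of yearly summer total biomass against baseline
    over the harvest periods; Mann-Kendall trends of emergence DOY and of
    the scenario-minus-baseline biomass difference.
    """
    stats_tables: dict[str, pd.DataFrame] = {}
    scenarios = sorted(biomass["scenario"].unique())
    years = config.analysis_years

    # replicate-mean yearly summer biomass per stream × scenario
    biom_mean = (
        biomass.groupby(["stream", "scenario", "year"])["biomass_g"]
        .mean().reset_index()
    )

    kw_rows, pw_rows, wx_rows, mk_rows = [], [], [], []
    mean_resp = responses.replicate_mean_responses()
    emerg_mean = (
        responses.emergence.groupby(["stream", "scenario", "year"])
        ["emergence_doy"].mean().reset_index()
    )

    for stream in config.streams:
        if len(scenarios) > 1:
            for (season, ac, var) in [
                (s, a, v)
                for s in ("summer", "winter")
                for a in (0, 1, 2, 3)
                for v in ("biomass_g", "growth_cm_per_month", "survival")
                if not (s == "winter" and a == 0)
            ]:
                groups, labels = [], []
                for scen in scenarios:
                    sel = mean_resp[
                        (mean_resp["stream"] == stream)
                        & (mean_resp["scenario"] == scen)
                        & (mean_resp["season"] == season)
                        & (mean_resp["age_class"] == ac)
                    ][var].dropna().to_numpy()
                    if sel.size:
                        groups.append(sel)
                        labels.append(scen)
                if len(groups) >= 2:
                    h, p = st.kruskal_wallis(*groups)
                    kw_rows.append((stream, season, ac, var, h, p))
                    if p <= 0.05:
                        pmat = st.pairwise_rank_tukey(groups, labels=labels)
                        for i, a_ in enumerate(labels):
                            for j in range(i + 1, len(labels)):
                                pw_rows.append(
                                    (stream, season, ac, var, a_, labels[j],
                                     float(pmat.iloc[i, j]))
                                )

        base = biom_mean[
            (biom_mean["stream"] == stream)
            & (biom_mean["scenario"].isin([s for s in scenarios
                                           if s == "baseline"]))
        ].set_index("year")["biomass_g"]
        for scen in scenarios:
            if scen == "baseline":
                continue
            alt = biom_mean[
                (biom_mean["stream"] == stream) & (biom_mean["scenario"] == scen)
            ].set_index("year")["biomass_g"]
            common = base.index.intersection(alt.index)
            periods = {
                k: (a, min(b, years)) for k, (a, b) in HARVEST_PERIODS.items()
            }
            for period, (a, b) in periods.items():
                yrs = [y for y in common if a <= y <= b]
                if len(yrs) >= 4:
                    res = st.wilcoxon_signed_rank(alt[yrs], base[yrs])
                    wx_rows.append(
                        (stream, scen, period, res.v, res.p, res.pseudomedian,
                         res.ci_low, res.ci_high)
                    )
                    diff = pd.DataFrame(
                        {"year": yrs,
                         "diff": (alt[yrs] - base[yrs]).to_numpy()}
                    )
                    trends = summarize_periods(
                        diff, "diff", windows={period: (a, b)},
                        analysis_years=years,
                    )
                    for wname, tr in trends.items():
                        mk_rows.append(
                            (stream, scen, "biomass_diff", wname, tr.s, tr.z,
                             tr.p, tr.sen_slope)
                        )

        for scen in scenarios:
            em = emerg_mean[
                (emerg_mean["stream"] == stream)
                & (emerg_mean["scenario"] == scen)
            ]
            trends = summarize_periods(em, "emergence_doy", analysis_years=years)
            for wname, tr in trends.items():
                mk_rows.append(
                    (stream, scen, "emergence_doy", wname, tr.s, tr.z, tr.p,
                     tr.sen_slope)
                )

    # percent change of scenario medians against baseline medians,
    # the shape of a seasonal response summary table
    pc_rows = []
    if "baseline" in scenarios and len(scenarios) > 1:
        for stream in config.streams:
            sub = mean_resp[mean_resp["stream"] == stream]
            for (season, ac, var) in [
                (s, a, v)
                for s in ("summer", "winter")
                for a in (0, 1, 2, 3)
                for v in ("biomass_g", "growth_cm_per_month", "survival")
                if not (s == "winter" and a == 0)
            ]:
                cell = sub[(sub["season"] == season) & (sub["age_class"] == ac)]
                base_med = cell[cell["scenario"] == "baseline"][var].median()
                for scen in scenarios:
                    if scen == "baseline":
                        continue
                    scen_med = cell[cell["scenario"] == scen][var].median()
                    if base_med and np.isfinite(base_med) and np.isfinite(scen_med):
                        pc = resp.percent_change(scen_med, base_med)
                    else:
                        pc = np.nan  # zero or missing baseline: undefined
                    pc_rows.append(
                        (stream, scen, season, ac, var, scen_med, base_med, pc)
                    )
    stats_tables["percent_change"] = pd.DataFrame(
        pc_rows, columns=["stream", "scenario", "season", "age_class",
                          "variable", "median_scenario", "median_baseline",
                          "percent_change"]
    )

    stats_tables["kruskal_wallis"] = pd.DataFrame(
        kw_rows, columns=["stream", "season", "age_class", "variable", "H", "p"]
    )
    stats_tables["pairwise"] = pd.DataFrame(
        pw_rows, columns=["stream", "season", "age_class", "variable",
                          "scenario_a", "scenario_b", "p"]
    )
    stats_tables["wilcoxon"] = pd.DataFrame(
        wx_rows, columns=["stream", "scenario", "period", "V", "p",
                          "pseudomedian", "ci_low", "ci_high"]
    )
    stats_tables["mann_kendall"] = pd.DataFrame(
        mk_rows, columns=["stream", "scenario", "variable", "window", "S", "Z",
                          "p", "sen_slope_per_decade"]
    )
    return stats_tables


def write_results(result: ExperimentResult, outdir) -> list[Path]:
    """Write all result tables as CSV, each with an embedded config hash."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = result.provenance["config_hash"]
    written = []

    def _write(df: pd.DataFrame, name: str):
        path = outdir / f"{name}.csv"
        with open(path, "w") as fh:
            fh.write(f"# config_hash={chash}\n")
            df.to_csv(fh, index=False)
        written.append(path)

    _write(result.responses.responses, "responses")
    _write(result.responses.emergence, "emergence")
    _write(result.summer_total_biomass, "summer_total_biomass")
    for name, df in result.statistics.items():
        _write(df, f"stats_{name}")
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(result.provenance, fh, indent=2, sort_keys=True)
    written.append(outdir / "provenance.json")
    return written


def read_result_csv(path) -> pd.DataFrame:
    """Read a result CSV written by :func:`write_results` (skips the hash line)."""
    return pd.read_csv(path, comment="#")
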