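"""The daily schedule and multi-year simulation driver.

Every simulated day executes, in order: spawning, habitat selection,
growth, survival, and egg development; the date then advances and ages
increment when the new date is January 1 (the fisheries convention — there
are no age-0 fish in winter).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..environment import ReachGeometry
from . import kernel
from .ops import fecundity, update_hydraulics
from .params import IbmParams
from .state import (
    MODE_DRIFT, MODE_SEARCH, SEX_F, SEX_M, DayInput, Redd, SimState, Trout,
)

DEATH_CAUSES = ("terrestrial_predation", "fish_predation", "starvation",
                "high_temperature", "stranding")


def init_state(
    reach: ReachGeometry, params: IbmParams, seed: int,
    start_date="2006-10-01",
) -> SimState:
    """Create a state with the configured per-age-class initial population.

    Lengths come from age-specific normals, weights from the reference
    condition relationship, cells from uniform random placement.
    """
    state = SimState(reach, seed=seed, date=pd.Timestamp(start_date))
    rng = state.rng
    mean = dict(params.init_len_mean)
    sd = dict(params.init_len_sd)
    for age, count in params.init_counts:
        if count <= 0:
            continue
        lengths = np.clip(rng.normal(mean[age], sd[age], count), 3.0, None)
        weights = params.condition_ref_a * lengths**3
        cells = rng.integers(0, reach.n_cells, count)
        sexes = rng.integers(0, 2, count)
        for i in range(count):
            state.add_fish(int(sexes[i]), age, 0.0, 0.0, int(cells[i]),
                           lengths=lengths[i : i + 1], weights=weights[i : i + 1])
    return state


def _in_spawn_window(date: pd.Timestamp, params: IbmParams) -> bool:
    md = (date.month, date.day)
    return (params.spawn_start_month, params.spawn_start_day) <= md <= (
        params.spawn_end_month, params.spawn_end_day,
    )


def spawn(state: SimState, day: DayInput, params: IbmParams) -> list[Redd]:
    """Spawning action: eligible females spawn with a daily Bernoulli draw.

    Eligibility: within the date window, temperature within bounds, flow
    below the threshold fraction of reference flow, female fork length at or
    above the minimum, not yet spawned this season.  A spawning female moves
    to the reach's best gravel cell (largest gravel fraction, ties to the
    lower id) and creates a redd holding ``fecundity(length)`` eggs; she and
    the largest eligible male each lose the spawning weight-loss fraction.
    """
    new_redds: list[Redd] = []
    if not _in_spawn_window(day.date, params):
        return new_redds
    if not (params.spawn_temp_min <= day.temp <= params.spawn_temp_max):
        return new_redds
    if day.flow >= params.spawn_max_flow_frac * state.ref_flow:
        return new_redds
    if state.cell_gravel[state.gravel_cell] <= 0.0:
        return new_redds
    eligible = (
        (state.fish_sex == SEX_F)
        & ~state.fish_spawned
        & (state.fish_len >= params.spawn_min_length)
    )
    idx = np.nonzero(eligible)[0]
    if idx.size == 0:
        return new_redds
    draws = state.rng.random(idx.size)
    spawners = idx[draws < params.spawn_prob]
    for i in spawners:
        length = float(state.fish_len[i])
        eggs = fecundity(length, params)
        redd = Redd(
            id=state.next_redd_id, cell=state.gravel_cell, eggs=eggs,
            eggs_initial=eggs, created=day.date,
        )
        state.next_redd_id += 1
        state.redds.append(redd)
        new_redds.append(redd)
        state.fish_wt[i] *= 1.0 - params.spawn_weight_loss
        state.fish_spawned[i] = True
        state.fish_cell[i] = state.gravel_cell
        state.spawn_log.append(
            (day.date, state.day_index, int(state.fish_id[i]), eggs)
        )
        # largest male not yet spent this season; he too pays the weight loss
        males = (
            (state.fish_sex == SEX_M)
            & ~state.fish_spawned
            & (state.fish_len >= params.spawn_min_length)
        )
        midx = np.nonzero(males)[0]
        if midx.size:
            m = midx[np.argmax(state.fish_len[midx])]
            state.fish_wt[m] *= 1.0 - params.spawn_weight_loss
            state.fish_spawned[m] = True
    return new_redds


def _hierarchy_order(state: SimState) -> np.ndarray:
    """Strictly decreasing length; ties broken by lower fish id."""
    return np.lexsort((state.fish_id, -state.fish_len))


def _fast_hydraulics(state: SimState, flow: float, dry_depth: float):
    """Vectorized power-law ratings on the state's precomputed cell arrays;
    same arithmetic as :func:`troutsim.ibm.ops.update_hydraulics`."""
    q = flow / state.ref_flow
    depth = state.cell_ref_depth * q**state.cell_dexp
    vel = state.cell_ref_vel * q**state.cell_vexp
    return depth, vel, depth >= dry_depth


def _run_day_kernel(state: SimState, day: DayInput, params: IbmParams,
                    par: np.ndarray | None = None):
    """Habitat selection + growth + survival probabilities for the whole
    population (the compiled hierarchy loop).  Returns per-fish arrays."""
    if par is None:
        par = params.pack()
    depth, vel, wetted = _fast_hydraulics(state, day.flow, params.dry_depth)
    drift_food = (
        params.drift_conc * vel * depth * state.cell_width * params.day_seconds
    )
    search_food = params.search_prod * state.cell_area
    n = state.n_fish
    out_cell = np.zeros(n, dtype=np.int64)
    out_mode = np.zeros(n, dtype=np.int64)
    out_dw = np.zeros(n)
    out_intake = np.zeros(n)
    out_psurv = np.ones(n)
    if n:
        order = _hierarchy_order(state)
        kernel.day_kernel(
            state.fish_len, state.fish_wt, order, depth, vel,
            state.cell_area, state.cell_shelter, state.cell_dist, wetted,
            drift_food, search_food, day.temp, day.turbidity, par,
            out_cell, out_mode, out_dw, out_intake, out_psurv,
        )
    return depth, vel, wetted, out_cell, out_mode, out_dw, out_intake, out_psurv


def select_habitat(state: SimState, day: DayInput, params: IbmParams) -> dict:
    """Assign every fish a (cell, mode); returns {fish_id: (cell, mode_name)}.

    Fish choose in decreasing length order (ties by id), each maximizing
    expected fitness given the food already claimed by larger fish.
    """
    _, _, _, cells, modes, _, _, _ = _run_day_kernel(state, day, params)
    state.fish_cell = cells.copy()
    state.fish_mode = modes.astype(np.int8)
    return {
        int(state.fish_id[i]): (
            int(cells[i]), "drift" if modes[i] == MODE_DRIFT else "search"
        )
        for i in range(state.n_fish)
    }


def _attribute_death(state, i, depth, wetted, day, params, larger):
    """Pick a cause of death, weighted by each source's risk in the cell."""
    par = params.pack()
    c = state.fish_cell[i]
    length = state.fish_len[i]
    weight = state.fish_wt[i]
    full = kernel.survival_probability(
        length, weight, depth[c], state.cell_dist[c], day.temp, True,
        larger, par,
    )
    # source-specific risks, same formulas as the combined probability
    s_each = np.empty(5)
    r_t = (
        params.terr_risk_max
        * _sig((params.terr_depth_half - depth[c]) / params.terr_depth_width)
        * _sig((state.cell_dist[c] - params.terr_dist_half) / params.terr_dist_width)
        * _sig((length - params.terr_len_half) / params.terr_len_width)
    )
    r_p = 0.0
    if larger:
        r_p = params.pisc_risk_max * _sig(
            (params.pisc_len_half - length) / params.pisc_len_width
        )
    k = weight / (params.condition_ref_a * length**3)
    r_s = 1.0 - _sig((k - params.starv_k_half) / params.starv_k_width)
    r_h = 1.0 - _sig((params.temp_surv_half - day.temp) / params.temp_surv_width)
    r_d = 0.0 if wetted[c] else 1.0 - params.strand_surv
    risks = np.array([r_t, r_p, r_s, r_h, r_d])
    if risks.sum() <= 0:
        return DEATH_CAUSES[0]
    probs = risks / risks.sum()
    return DEATH_CAUSES[int(state.rng.choice(5, p=probs))]


def _sig(x):
    x = float(np.clip(x, -35.0, 35.0))
    return 1.0 / (1.0 + np.exp(-x))


def develop_redds(state: SimState, day: DayInput, params: IbmParams,
                  depth=None, wetted=None) -> int:
    """Egg development and mortality; returns the number of fry emerged today.

    Development advances by max(T, 0)/degree-day requirement.  Eggs die from
    a baseline daily binomial, total scour loss when flow exceeds the scour
    threshold, total desiccation when the redd's cell is dry, and an extra
    binomial outside the temperature tolerance band.  Fully developed redds
    convert surviving eggs into age-0 fish with normal emergence lengths.
    """
    if depth is None:
        depth, _, wetted = update_hydraulics(state.reach, day.flow)
    emerged_total = 0
    rng = state.rng
    still_open: list[Redd] = []
    for redd in state.redds:
        if redd.eggs > 0:
            if day.flow > params.scour_flow_frac * state.ref_flow:
                redd.dead += redd.eggs
                redd.eggs = 0
            elif not wetted[redd.cell]:
                redd.dead += redd.eggs
                redd.eggs = 0
            else:
                p = params.egg_daily_mort
                if not (params.egg_temp_min <= day.temp <= params.egg_temp_max):
                    p = min(1.0, p + params.egg_temp_mort)
                deaths = int(rng.binomial(redd.eggs, p))
                redd.eggs -= deaths
                redd.dead += deaths
        redd.dev = min(redd.dev + max(day.temp, 0.0) / params.egg_dd_req, 1.0)
        if redd.dev >= 1.0 - 1e-12:
            if redd.eggs > 0:
                n = redd.eggs
                lengths = np.clip(
                    rng.normal(params.fry_len_mean, params.fry_len_sd, n),
                    0.5, None,
                )
                weights = params.condition_ref_a * lengths**3
                state.add_fish(SEX_F, 0, 0.0, 0.0, redd.cell,
                               lengths=lengths, weights=weights)
                # emergent sex ratio 1:1, drawn per fish
                sexes = rng.integers(0, 2, n).astype(np.int8)
                state.fish_sex[-n:] = sexes
                redd.emerged = n
                redd.eggs = 0
                emerged_total += n
                state.emergence_log.append((day.date, state.day_index, n))
            state.closed_redds.append(redd)
        elif redd.eggs == 0 and redd.dev < 1.0:
            state.closed_redds.append(redd)
        else:
            still_open.append(redd)
    state.redds = still_open
    return emerged_total


def age_increment(state: SimState, date: pd.Timestamp) -> None:
    """Add one year to every fish; only valid on January 1.

    Also resets the spawned-this-season flags for the new calendar year.
    """
    date = pd.Timestamp(date)
    if (date.month, date.day) != (1, 1):
        raise ValueError("age_increment may only be called on January 1")
    state.fish_age = state.fish_age + 1
    state.fish_spawned[:] = False


def daily_step(state: SimState, day: DayInput, params: IbmParams) -> SimState:
    """Execute one day: spawning, habitat selection, growth, survival, egg
    development; then advance the date (ages increment when it reaches
    January 1)."""
    state.record("spawning")
    spawn(state, day, params)

    state.record("habitat_selection")
    depth, vel, wetted, cells, modes, dw, intake, psurv = _run_day_kernel(
        state, day, params
    )
    state.fish_cell = cells
    state.fish_mode = modes.astype(np.int8)

    state.record("growth")
    if state.n_fish:
        state.fish_wt = state.fish_wt + dw
        wref = params.condition_ref_a * state.fish_len**3
        over = state.fish_wt > wref
        if over.any():
            state.fish_len = np.where(
                over, (state.fish_wt / params.condition_ref_a) ** (1.0 / 3.0),
                state.fish_len,
            )

    state.record("survival")
    if state.n_fish:
        u = state.rng.random(state.n_fish)
        dead = u >= psurv
        if dead.any():
            order = _hierarchy_order(state)
            top_len = state.fish_len[order[0]]
            causes: dict[str, int] = {}
            for i in np.nonzero(dead)[0]:
                larger = top_len >= params.pisc_size_ratio * state.fish_len[i]
                cause = _attribute_death(state, i, depth, wetted, day, params,
                                         larger)
                causes[cause] = causes.get(cause, 0) + 1
            for cause, count in sorted(causes.items()):
                state.death_log.append((day.date, state.day_index, cause, count))
            state.remove_fish(~dead)

    state.record("egg_development")
    develop_redds(state, day, params, depth, wetted)

    state.day_index += 1
    state.date = day.date + pd.Timedelta(days=1)
    if (state.date.month, state.date.day) == (1, 1):
        age_increment(state, state.date)
    return state


@dataclass
class SimOutput:
    """Periodic population snapshots plus event logs from one replicate."""

    snapshots: pd.DataFrame  # date, day_index, fish_id, age, length, weight, cell
    emergence: pd.DataFrame  # date, day_index, count
    deaths: pd.DataFrame  # date, day_index, cause, count
    spawns: pd.DataFrame  # date, day_index, female_id, eggs
    state: SimState

    def write_csv(self, outdir) -> None:
        """Write the snapshot table and event logs as CSV files."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.snapshots.to_csv(outdir / "snapshots.csv", index=False)
        self.emergence.to_csv(outdir / "emergence_events.csv", index=False)
        self.deaths.to_csv(outdir / "death_events.csv", index=False)
        self.spawns.to_csv(outdir / "spawn_events.csv", index=False)


def run_simulation(
    reach: ReachGeometry,
    regime: pd.DataFrame,
    params: IbmParams,
    seed: int,
    output_every: int = 30,
    audit: bool = False,
) -> SimOutput:
    """Run the IBM over a regime series, snapshotting every ``output_every`` days."""
    state = init_state(reach, params, seed,
                       start_date=pd.Timestamp(regime["date"].iloc[0]))
    if audit:
        state.audit = []

    dates = pd.to_datetime(regime["date"]).to_numpy()
    flows = regime["flow_m3s"].to_numpy(float)
    temps = regime["temp_c"].to_numpy(float)
    turbs = regime["turbidity_ntu"].to_numpy(float)

    snap_rows = []
    for t in range(len(regime)):
        if t % output_every == 0 and state.n_fish:
            snap_rows.append(
                pd.DataFrame(
                    {
                        "date": dates[t],
                        "day_index": t,
                        "fish_id": state.fish_id,
                        "age": state.fish_age,
                        "length": state.fish_len,
                        "weight": state.fish_wt,
                        "cell": state.fish_cell,
                    }
                )
            )
        day = DayInput(date=pd.Timestamp(dates[t]), flow=flows[t],
                       temp=temps[t], turbidity=turbs[t])
        daily_step(state, day, params)

    snapshots = (
        pd.concat(snap_rows, ignore_index=True)
        if snap_rows
        else pd.DataFrame(
            columns=["date", "day_index", "fish_id", "age", "length",
                     "weight", "cell"]
        )
    )
    emergence = pd.DataFrame(
        state.emergence_log, columns=["date", "day_index", "count"]
    )
    deaths = pd.DataFrame(
        state.death_log, columns=["date", "day_index", "cause", "count"]
    )
    spawns = pd.DataFrame(
        state.spawn_log, columns=["date", "day_index", "female_id", "eggs"]
    )
    return SimOutput(snapshots=snapshots, emergence=emergence, deaths=deaths,
                     spawns=spawns, state=state)
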