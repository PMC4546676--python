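"""Reference per-fish operations of the trout model.

These are the contract-level operations — hydraulics, fecundity, expected
fitness, growth, survival — expressed one fish and one cell at a time.
They evaluate the same compiled scalar formulas as the daily kernel
(:mod:`troutsim.ibm.kernel`), so the fast path and this surface cannot
drift apart; tests additionally assert the kernel's habitat assignment
equals a brute-force argmax over these functions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ..environment import ReachGeometry
from . import kernel
from .params import IbmParams
from .state import DayInput, Trout

_MODE_CODE = {"drift": kernel.DRIFT, "search": kernel.SEARCH}


@dataclass
class CellDay:
    """A cell's state on one day: hydraulics plus remaining food."""

    cell_id: int
    depth: float  # m
    velocity: float  # m/s
    area: float  # m²
    shelter_fraction: float
    gravel_fraction: float
    dist_cover: float  # m
    wetted: bool
    drift_food: float  # g remaining today
    search_food: float  # g remaining today


def update_hydraulics(reach: ReachGeometry, flow: float, dry_depth: float = 0.01):
    """Per-cell depth (m), velocity (m/s) and wetted flags at the given flow.

    Power-law ratings anchored at the reference flow:
    ``depth = ref_depth · (Q/Qref)^depth_exp`` and likewise for velocity.
    Cells shallower than ``dry_depth`` (default 1 cm) are dry.
    """
    if flow <= 0:
        raise ValueError("flow must be positive")
    q = flow / reach.ref_flow
    depth = np.array([c.ref_depth * q**c.depth_exponent for c in reach.cells])
    vel = np.array([c.ref_velocity * q**c.velocity_exponent for c in reach.cells])
    wetted = depth >= dry_depth
    return depth, vel, wetted


def daily_cell_food(reach: ReachGeometry, depth, vel, params: IbmParams):
    """Per-cell depletable food for one day.

    Drift food is the mass of drifting invertebrates transported through the
    cell cross-section during the foraging day; search food is benthic
    production over the cell area.
    """
    cell_len = reach.reach_length / reach.n_cells
    widths = np.array([c.area for c in reach.cells]) / cell_len
    drift = params.drift_conc * vel * depth * widths * params.day_seconds
    search = params.search_prod * np.array([c.area for c in reach.cells])
    return drift, search


def fecundity(length: float, params: IbmParams) -> int:
    """Egg count of a spawning female: round(a · L^b), increasing in length."""
    if length <= 0:
        raise ValueError("length must be positive")
    return int(round(params.fecundity_a * length**params.fecundity_b))


def expected_fitness(
    trout: Trout, cell: CellDay, mode: str, day: DayInput,
    params: IbmParams, larger_present: bool = False,
) -> float:
    """Expected 90-day fitness for one fish in one cell and feeding mode.

    ``survival^horizon`` times the projected-condition term (projected weight
    after the horizon at the cell's net growth rate, relative to reference
    weight, clamped to [eps, 1]).  Dry cells score 0.
    """
    if not cell.wetted:
        return 0.0
    f, _, _ = kernel.fitness_value(
        trout.length, trout.weight, cell.depth, cell.velocity, cell.area,
        cell.shelter_fraction, cell.dist_cover, day.temp, day.turbidity,
        cell.drift_food, cell.search_food, True, larger_present,
        _MODE_CODE[mode], params.pack(),
    )
    return float(f)


def grow(
    trout: Trout, cell: CellDay, mode: str, day: DayInput, params: IbmParams
) -> Trout:
    """Apply one day's energy budget: weight from net energy; length grows
    only while condition stays at or above 1 (condition is never pushed
    above 1 by a length increase)."""
    dw, _ = kernel.net_growth(
        trout.length, trout.weight, cell.velocity, cell.depth,
        cell.shelter_fraction, day.temp, day.turbidity,
        cell.drift_food, cell.search_food, _MODE_CODE[mode], params.pack(),
    )
    wref = params.ref_weight(trout.length)
    new_w = max(trout.weight + dw, params.weight_floor_frac * wref)
    new_len = trout.length
    if new_w > wref:  # condition above 1: convert surplus into length at K = 1
        new_len = (new_w / params.condition_ref_a) ** (1.0 / 3.0)
    return replace(trout, weight=new_w, length=new_len)


def survival_probability(
    trout: Trout, cell: CellDay, day: DayInput, params: IbmParams,
    larger_present: bool = False,
) -> float:
    """Combined daily survival probability for one fish in its cell."""
    return float(
        kernel.survival_probability(
            trout.length, trout.weight, cell.depth, cell.dist_cover, day.temp,
            cell.wetted, larger_present, params.pack(),
        )
    )


def survive(
    trout: Trout, cell: CellDay, day: DayInput, params: IbmParams,
    rng: np.random.Generator, larger_present: bool = False,
) -> bool:
    """One Bernoulli survival draw at the fish's combined daily probability."""
    p = survival_probability(trout, cell, day, params, larger_present)
    return bool(rng.random() < p)


def make_cell_days(reach: ReachGeometry, day: DayInput, params: IbmParams):
    """Build the per-cell daily state (hydraulics + food) for reference ops."""
    depth, vel, wetted = update_hydraulics(reach, day.flow)
    drift, search = daily_cell_food(reach, depth, vel, params)
    return [
        CellDay(
            cell_id=c.cell_id, depth=float(depth[i]), velocity=float(vel[i]),
            area=c.area, shelter_fraction=c.shelter_fraction,
            gravel_fraction=c.gravel_fraction, dist_cover=c.dist_cover,
            wetted=bool(wetted[i]), drift_food=float(drift[i]),
            search_food=float(search[i]),
        )
        for i, c in enumerate(reach.cells)
    ]
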