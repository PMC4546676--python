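"""Simulation state containers: individual fish, redds, and the daily state.

The population lives in struct-of-arrays storage inside :class:`SimState`
for speed; :class:`Trout` is the per-individual view used by the reference
operations and in tests.  Redds are few at any time and stay as objects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..environment import ReachGeometry

SEX_F = 0
SEX_M = 1
MODE_DRIFT = 0
MODE_SEARCH = 1


@dataclass
class Trout:
    """One fish. ``mode`` is 'drift' or 'search'; age increments each Jan 1."""

    id: int
    sex: str  # 'F' | 'M'
    age: int
    length: float  # cm fork length
    weight: float  # g
    cell: int
    mode: str = "drift"
    spawned: bool = False  # reset each Jan 1; females spawn once per year
    alive: bool = True

    def __post_init__(self):
        if self.length <= 0 or self.weight <= 0:
            raise ValueError("length and weight must be positive")


@dataclass
class Redd:
    """An egg pocket: egg count and degree-day development state."""

    id: int
    cell: int
    eggs: int
    eggs_initial: int
    dev: float = 0.0  # development fraction, 0–1
    created: pd.Timestamp | None = None
    dead: int = 0  # cumulative egg deaths
    emerged: int = 0  # cumulative emerged fry


@dataclass(frozen=True)
class DayInput:
    """One day's environmental driver."""

    date: pd.Timestamp
    flow: float  # m³/s
    temp: float  # °C
    turbidity: float  # NTU

    @classmethod
    def from_row(cls, row) -> "DayInput":
        return cls(
            date=pd.Timestamp(row.date), flow=float(row.flow_m3s),
            temp=float(row.temp_c), turbidity=float(row.turbidity_ntu),
        )


class SimState:
    """Mutable daily state: reach arrays, fish arrays, redds, date, RNG.

    Stochastic draws consume the single ``rng`` in a fixed daily order
    (spawning Bernoullis, survival uniforms, death-cause attribution, egg
    mortality, fry lengths at emergence) so runs are reproducible per seed.
    """

    def __init__(self, reach: ReachGeometry, seed: int, date: pd.Timestamp):
        self.reach = reach
        self.rng = np.random.default_rng(seed)
        self.date = pd.Timestamp(date)
        self.day_index = 0

        cells = reach.cells
        self.cell_area = np.array([c.area for c in cells])
        self.cell_ref_depth = np.array([c.ref_depth for c in cells])
        self.cell_ref_vel = np.array([c.ref_velocity for c in cells])
        self.cell_dexp = np.array([c.depth_exponent for c in cells])
        self.cell_vexp = np.array([c.velocity_exponent for c in cells])
        self.cell_shelter = np.array([c.shelter_fraction for c in cells])
        self.cell_gravel = np.array([c.gravel_fraction for c in cells])
        self.cell_dist = np.array([c.dist_cover for c in cells])
        self.ref_flow = reach.ref_flow
        self.cell_width = self.cell_area / (reach.reach_length / len(cells))
        # preferred spawning cell: largest gravel fraction, ties by lower id
        self.gravel_cell = int(np.argmax(self.cell_gravel))

        n0 = 0
        self.fish_id = np.zeros(n0, dtype=np.int64)
        self.fish_sex = np.zeros(n0, dtype=np.int8)
        self.fish_age = np.zeros(n0, dtype=np.int32)
        self.fish_len = np.zeros(n0)
        self.fish_wt = np.zeros(n0)
        self.fish_cell = np.zeros(n0, dtype=np.int64)
        self.fish_mode = np.zeros(n0, dtype=np.int8)
        self.fish_spawned = np.zeros(n0, dtype=bool)
        self.next_fish_id = 0

        self.redds: list[Redd] = []
        self.next_redd_id = 0

        # event logs (lists of tuples, converted to frames on demand)
        self.emergence_log: list[tuple] = []  # (date, day_index, count)
        self.death_log: list[tuple] = []  # (date, day_index, cause, count)
        self.spawn_log: list[tuple] = []  # (date, day_index, female_id, eggs)
        self.closed_redds: list[Redd] = []
        self.audit: list[tuple] | None = None  # (day_index, action) when enabled

    # -- population access ---------------------------------------------------
    @property
    def n_fish(self) -> int:
        return self.fish_id.size

    @property
    def total_biomass(self) -> float:
        return float(self.fish_wt.sum())

    def living_trout(self) -> list[Trout]:
        return [
            Trout(
                id=int(self.fish_id[i]),
                sex="F" if self.fish_sex[i] == SEX_F else "M",
                age=int(self.fish_age[i]),
                length=float(self.fish_len[i]),
                weight=float(self.fish_wt[i]),
                cell=int(self.fish_cell[i]),
                mode="drift" if self.fish_mode[i] == MODE_DRIFT else "search",
                spawned=bool(self.fish_spawned[i]),
            )
            for i in range(self.n_fish)
        ]

    def add_fish(self, sex: int, age: int, length: float, weight: float,
                 cell: int, n: int = 1, lengths=None, weights=None) -> None:
        """Append n fish (vectorized when lengths/weights arrays given)."""
        if lengths is None:
            lengths = np.full(n, length)
            weights = np.full(n, weight)
        else:
            n = len(lengths)
        ids = np.arange(self.next_fish_id, self.next_fish_id + n, dtype=np.int64)
        self.next_fish_id += n
        self.fish_id = np.concatenate([self.fish_id, ids])
        self.fish_sex = np.concatenate(
            [self.fish_sex, np.full(n, sex, dtype=np.int8)]
        )
        self.fish_age = np.concatenate(
            [self.fish_age, np.full(n, age, dtype=np.int32)]
        )
        self.fish_len = np.concatenate([self.fish_len, np.asarray(lengths, float)])
        self.fish_wt = np.concatenate([self.fish_wt, np.asarray(weights, float)])
        self.fish_cell = np.concatenate(
            [self.fish_cell, np.full(n, cell, dtype=np.int64)]
        )
        self.fish_mode = np.concatenate(
            [self.fish_mode, np.zeros(n, dtype=np.int8)]
        )
        self.fish_spawned = np.concatenate(
            [self.fish_spawned, np.zeros(n, dtype=bool)]
        )

    def remove_fish(self, keep_mask: np.ndarray) -> None:
        for name in ("fish_id", "fish_sex", "fish_age", "fish_len", "fish_wt",
                     "fish_cell", "fish_mode", "fish_spawned"):
            setattr(self, name, getattr(self, name)[keep_mask])

    def record(self, action: str) -> None:
        if self.audit is not None:
            self.audit.append((self.day_index, action))
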