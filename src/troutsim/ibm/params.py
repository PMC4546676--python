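"""Tunable parameters of the individual-based model.

All coefficients live here with units and defaults sized for a small
(≲0.1 m³/s summer baseflow) coastal cutthroat stream.  The packed-array
helpers at the bottom exist so the numba kernel and the pure-Python
reference operations evaluate the identical parameter values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class IbmParams:
    # --- spawning ---
    spawn_start_month: int = 4  # window Apr 1 – Jun 15
    spawn_start_day: int = 1
    spawn_end_month: int = 6
    spawn_end_day: int = 15
    spawn_temp_min: float = 5.0  # °C
    spawn_temp_max: float = 17.0  # °C
    spawn_max_flow_frac: float = 2.0  # × reach reference flow
    spawn_min_length: float = 12.0  # cm, minimum female fork length
    spawn_prob: float = 0.1  # daily Bernoulli once conditions are met
    fecundity_a: float = 0.2  # eggs = round(a · L^b), L in cm
    fecundity_b: float = 2.3
    spawn_weight_loss: float = 0.20  # fraction of body weight per spawner

    # --- condition / fitness ---
    condition_ref_a: float = 0.01  # g/cm³; reference weight = a·L³
    fitness_horizon: int = 90  # days
    fitness_eps: float = 1e-12  # fitness floor (dry cells score 0 separately)

    # --- feeding & bioenergetics ---
    drift_conc: float = 2.5e-4  # g dry food per m³ of drifting water
    search_prod: float = 0.15  # g food per m² per day (benthic production)
    day_seconds: float = 50000.0  # daytime foraging seconds per day
    capture_area_coef: float = 20.0  # capture area = coef·(L/100)² m²
    max_swim_lengths: float = 2.0  # body lengths/s; v_max = 0.02·L m/s
    capture_v_width_frac: float = 0.5  # logistic width as fraction of v_max
    turb_half: float = 30.0  # NTU at which capture success halves
    turb_width: float = 10.0  # NTU logistic width
    search_rate_a: float = 0.06  # g/day per g^0.8, search-feeding harvest rate
    cmax_a: float = 0.10  # g food/day per g^0.8
    cmax_t_opt: float = 14.0  # °C, dome peak of max consumption
    cmax_t_sd: float = 5.0  # °C, dome width
    met_a: float = 35.0  # J/day per g^0.8, resting metabolism at 0 °C
    met_t_coef: float = 0.07  # per °C, exponential temperature response
    act_cost: float = 1.0  # activity multiplier at v = v_max
    shelter_act_reduction: float = 0.5  # shelter halves activity cost
    search_act: float = 0.3  # constant activity multiplier for search feeding
    e_food: float = 3500.0  # J per g food
    e_tissue: float = 5900.0  # J per g wet tissue
    weight_floor_frac: float = 0.10  # of reference weight; starvation floor

    # --- survival (all daily probabilities) ---
    terr_risk_max: float = 0.004  # terrestrial predation, max daily risk
    terr_depth_half: float = 0.45  # m; shallower water is riskier
    terr_depth_width: float = 0.15  # m
    terr_dist_half: float = 5.0  # m; farther from cover is riskier
    terr_dist_width: float = 2.0  # m
    terr_len_half: float = 7.0  # cm; larger fish more exposed
    terr_len_width: float = 2.0  # cm
    pisc_risk_max: float = 0.015  # predation by larger trout, max daily risk
    pisc_len_half: float = 5.0  # cm; smaller fish more vulnerable
    pisc_len_width: float = 1.5  # cm
    pisc_size_ratio: float = 1.5  # predator must be ≥ ratio × own length
    starv_k_half: float = 0.6  # condition factor at 50 % daily survival
    starv_k_width: float = 0.05
    temp_surv_half: float = 25.0  # °C, logistic midpoint of thermal survival
    temp_surv_width: float = 1.0  # °C
    strand_surv: float = 0.2  # extra daily survival multiplier in a dry cell
    dry_depth: float = 0.01  # m; cells shallower than this are dry

    # --- eggs & emergence ---
    egg_dd_req: float = 450.0  # °C·days to full development
    egg_daily_mort: float = 0.05  # baseline daily egg mortality
    egg_temp_min: float = 2.0  # °C tolerance band
    egg_temp_max: float = 16.0
    egg_temp_mort: float = 0.05  # extra daily mortality outside the band
    scour_flow_frac: float = 10.0  # × reference flow; above → redd scoured
    fry_len_mean: float = 2.8  # cm at emergence
    fry_len_sd: float = 0.2

    # --- initialization (counts per age, lengths from age-specific normals) ---
    init_counts: tuple[tuple[int, int], ...] = ((1, 30), (2, 15), (3, 8))
    init_len_mean: tuple[tuple[int, float], ...] = ((1, 8.0), (2, 13.0), (3, 18.0))
    init_len_sd: tuple[tuple[int, float], ...] = ((1, 1.0), (2, 1.5), (3, 2.0))

    def ref_weight(self, length: float) -> float:
        """Weight (g) of a fish at reference condition (K = 1)."""
        return self.condition_ref_a * length**3

    # ---- packing for the numba kernel ----
    _PACK_FIELDS = (
        "condition_ref_a", "fitness_horizon", "fitness_eps",
        "drift_conc", "search_prod", "day_seconds", "capture_area_coef",
        "max_swim_lengths", "capture_v_width_frac", "turb_half", "turb_width",
        "search_rate_a", "cmax_a", "cmax_t_opt", "cmax_t_sd",
        "met_a", "met_t_coef", "act_cost", "shelter_act_reduction",
        "search_act", "e_food", "e_tissue", "weight_floor_frac",
        "terr_risk_max", "terr_depth_half", "terr_depth_width",
        "terr_dist_half", "terr_dist_width", "terr_len_half", "terr_len_width",
        "pisc_risk_max", "pisc_len_half", "pisc_len_width", "pisc_size_ratio",
        "starv_k_half", "starv_k_width", "temp_surv_half", "temp_surv_width",
        "strand_surv", "dry_depth",
    )

    def pack(self) -> np.ndarray:
        return np.array([float(getattr(self, f)) for f in self._PACK_FIELDS])


# index constants into IbmParams.pack(); order must match _PACK_FIELDS
for _i, _f in enumerate(IbmParams._PACK_FIELDS):
    globals()["P_" + _f.upper()] = _i
del _i, _f
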