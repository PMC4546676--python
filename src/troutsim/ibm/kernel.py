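"""Numba-compiled daily core: habitat choice, growth and survival math.

The scalar functions here are the single source of truth for the
bioenergetics and survival formulas: the pure-Python operations in
:mod:`troutsim.ibm.ops` call them one fish at a time, and
:func:`day_kernel` runs the same functions inside the compiled
length-hierarchy loop that processes the whole population each day.

Parameters arrive packed as a float64 array (see ``IbmParams.pack``);
``mode`` is 0 for drift feeding and 1 for search feeding.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .params import (  # noqa: F401  (index constants generated in params.py)
    P_CONDITION_REF_A, P_FITNESS_HORIZON, P_FITNESS_EPS,
    P_DRIFT_CONC, P_SEARCH_PROD, P_DAY_SECONDS, P_CAPTURE_AREA_COEF,
    P_MAX_SWIM_LENGTHS, P_CAPTURE_V_WIDTH_FRAC, P_TURB_HALF, P_TURB_WIDTH,
    P_SEARCH_RATE_A, P_CMAX_A, P_CMAX_T_OPT, P_CMAX_T_SD,
    P_MET_A, P_MET_T_COEF, P_ACT_COST, P_SHELTER_ACT_REDUCTION,
    P_SEARCH_ACT, P_E_FOOD, P_E_TISSUE, P_WEIGHT_FLOOR_FRAC,
    P_TERR_RISK_MAX, P_TERR_DEPTH_HALF, P_TERR_DEPTH_WIDTH,
    P_TERR_DIST_HALF, P_TERR_DIST_WIDTH, P_TERR_LEN_HALF, P_TERR_LEN_WIDTH,
    P_PISC_RISK_MAX, P_PISC_LEN_HALF, P_PISC_LEN_WIDTH, P_PISC_SIZE_RATIO,
    P_STARV_K_HALF, P_STARV_K_WIDTH, P_TEMP_SURV_HALF, P_TEMP_SURV_WIDTH,
    P_STRAND_SURV, P_DRY_DEPTH,
)

DRIFT = 0
SEARCH = 1


@njit(cache=True)
def _sigmoid(x):
    if x > 35.0:
        return 1.0
    if x < -35.0:
        return 0.0
    return 1.0 / (1.0 + math.exp(-x))


@njit(cache=True)
def capture_success(v, turb, length, par):
    """Probability of capturing encountered drift; declines with velocity
    (relative to the fish's sustainable swim speed) and with turbidity."""
    vmax = par[P_MAX_SWIM_LENGTHS] * length / 100.0  # m/s
    width = par[P_CAPTURE_V_WIDTH_FRAC] * vmax + 1e-9
    s_v = _sigmoid((vmax - v) / width)
    s_t = _sigmoid((par[P_TURB_HALF] - turb) / par[P_TURB_WIDTH])
    return s_v * s_t


@njit(cache=True)
def cmax(weight, temp, par):
    """Maximum daily food consumption (g): allometric with a thermal dome."""
    d = (temp - par[P_CMAX_T_OPT]) / par[P_CMAX_T_SD]
    return par[P_CMAX_A] * weight**0.8 * math.exp(-0.5 * d * d)


@njit(cache=True)
def metabolism(weight, temp, velocity, shelter, length, mode, par):
    """Daily energy cost (J): resting metabolism times an activity factor.

    Drift feeding pays a swimming cost rising with velocity relative to the
    fish's maximum sustainable speed, reduced by velocity shelter; search
    feeding pays a constant activity surcharge.
    """
    rest = par[P_MET_A] * weight**0.8 * math.exp(par[P_MET_T_COEF] * temp)
    if mode == DRIFT:
        vmax = par[P_MAX_SWIM_LENGTHS] * length / 100.0
        rel = velocity / vmax
        if rel > 3.0:
            rel = 3.0
        act = 1.0 + par[P_ACT_COST] * rel * (
            1.0 - par[P_SHELTER_ACT_REDUCTION] * shelter
        )
    else:
        act = 1.0 + par[P_SEARCH_ACT]
    return rest * act


@njit(cache=True)
def intake_potential(length, weight, velocity, depth, temp, turb,
                     drift_avail, search_avail, mode, par):
    """Daily food intake (g) in a cell: encounter/harvest rate capped by
    maximum consumption and by food remaining in the cell."""
    cm = cmax(weight, temp, par)
    if mode == DRIFT:
        area = par[P_CAPTURE_AREA_COEF] * (length / 100.0) ** 2
        enc = par[P_DRIFT_CONC] * velocity * area * par[P_DAY_SECONDS]
        pot = enc * capture_success(velocity, turb, length, par)
        avail = drift_avail
    else:
        pot = par[P_SEARCH_RATE_A] * weight**0.8
        avail = search_avail
    if pot > cm:
        pot = cm
    if pot > avail:
        pot = avail
    if pot < 0.0:
        pot = 0.0
    return pot


@njit(cache=True)
def net_growth(length, weight, velocity, depth, shelter, temp, turb,
               drift_avail, search_avail, mode, par):
    """Daily weight change (g) and intake (g food) for a fish in a cell."""
    intake = intake_potential(length, weight, velocity, depth, temp, turb,
                              drift_avail, search_avail, mode, par)
    energy = intake * par[P_E_FOOD] - metabolism(
        weight, temp, velocity, shelter, length, mode, par
    )
    return energy / par[P_E_TISSUE], intake


@njit(cache=True)
def survival_probability(length, weight, depth, dist_cover, temp, wetted,
                         larger_present, par):
    """Combined daily survival: terrestrial predation × piscine predation ×
    starvation × high temperature, times a stranding penalty in dry cells."""
    # terrestrial predation: risky when shallow, far from cover, and large
    r_t = (
        par[P_TERR_RISK_MAX]
        * _sigmoid((par[P_TERR_DEPTH_HALF] - depth) / par[P_TERR_DEPTH_WIDTH])
        * _sigmoid((dist_cover - par[P_TERR_DIST_HALF]) / par[P_TERR_DIST_WIDTH])
        * _sigmoid((length - par[P_TERR_LEN_HALF]) / par[P_TERR_LEN_WIDTH])
    )
    s = 1.0 - r_t
    # predation by larger trout: risky when small and a large fish is present
    if larger_present:
        r_p = par[P_PISC_RISK_MAX] * _sigmoid(
            (par[P_PISC_LEN_HALF] - length) / par[P_PISC_LEN_WIDTH]
        )
        s *= 1.0 - r_p
    # starvation / disease through condition factor
    k = weight / (par[P_CONDITION_REF_A] * length**3)
    s *= _sigmoid((k - par[P_STARV_K_HALF]) / par[P_STARV_K_WIDTH])
    # high temperature
    s *= _sigmoid((par[P_TEMP_SURV_HALF] - temp) / par[P_TEMP_SURV_WIDTH])
    if not wetted:
        s *= par[P_STRAND_SURV]
    return s


@njit(cache=True)
def fitness_value(length, weight, depth, velocity, area, shelter, dist_cover,
                  temp, turb, drift_avail, search_avail, wetted,
                  larger_present, mode, par):
    """Expected 90-day fitness of occupying one cell in one feeding mode.

    survival^horizon × a condition projection: the ratio of the weight
    projected after `horizon` days at the cell's net growth rate to the
    reference weight at the fish's length, clamped to [eps, 1].
    Returns (fitness, daily_dW, daily_intake); dry cells score 0.
    """
    if not wetted:
        return 0.0, 0.0, 0.0
    dw, intake = net_growth(length, weight, velocity, depth, shelter, temp,
                            turb, drift_avail, search_avail, mode, par)
    wref = par[P_CONDITION_REF_A] * length**3
    wproj = weight + par[P_FITNESS_HORIZON] * dw
    floor = par[P_WEIGHT_FLOOR_FRAC] * wref
    if wproj < floor:
        wproj = floor
    kproj = wproj / wref
    p = survival_probability(length, wproj, depth, dist_cover, temp, True,
                             larger_present, par)
    cond_term = kproj if kproj < 1.0 else 1.0
    f = p ** par[P_FITNESS_HORIZON] * cond_term
    if f < par[P_FITNESS_EPS]:
        f = par[P_FITNESS_EPS]
    return f, dw, intake


@njit(cache=True)
def day_kernel(lengths, weights, order, depth, velocity, area, shelter,
               dist_cover, wetted, drift_food, search_food, temp, turb, par,
               out_cell, out_mode, out_dw, out_intake, out_psurv):
    """One day of habitat selection, growth and survival probability.

    Fish are processed in the hierarchy `order` (descending length, ties by
    id): each picks the wetted (cell, mode) maximizing the expected-fitness
    score given food already claimed by earlier fish, claims its intake from
    the cell's food, grows by the realized energy budget, and gets a
    post-growth daily survival probability at the chosen cell.  If every
    cell is dry, fish shelter in the deepest cell with no intake and the
    stranding penalty.  Mutates `drift_food`/`search_food`; writes per-fish
    outputs in place.

    The math matches the scalar functions above (`fitness_value`,
    `net_growth`, `survival_probability`); quantities that do not vary per
    fish×cell (thermal survival, per-cell terrestrial exposure, drift
    encounter bases) are hoisted out of the inner loop for speed.
    """
    n = lengths.size
    nc = depth.size
    any_wet = False
    deepest = 0
    for c in range(nc):
        if wetted[c]:
            any_wet = True
        if depth[c] > depth[deepest]:
            deepest = c
    top_len = 0.0
    if n > 0:
        top_len = lengths[order[0]]

    # per-day terms
    s_temp = _sigmoid((par[P_TEMP_SURV_HALF] - temp) / par[P_TEMP_SURV_WIDTH])
    s_turb = _sigmoid((par[P_TURB_HALF] - turb) / par[P_TURB_WIDTH])
    horizon = par[P_FITNESS_HORIZON]
    e_t = par[P_E_TISSUE]

    # per-cell terms
    terr_cell = np.empty(nc)
    drift_base = np.empty(nc)
    for c in range(nc):
        terr_cell[c] = par[P_TERR_RISK_MAX] * _sigmoid(
            (par[P_TERR_DEPTH_HALF] - depth[c]) / par[P_TERR_DEPTH_WIDTH]
        ) * _sigmoid(
            (dist_cover[c] - par[P_TERR_DIST_HALF]) / par[P_TERR_DIST_WIDTH]
        )
        drift_base[c] = par[P_DRIFT_CONC] * velocity[c] * par[P_DAY_SECONDS]

    for k in range(n):
        i = order[k]
        length = lengths[i]
        weight = weights[i]
        larger = k > 0 and top_len >= par[P_PISC_SIZE_RATIO] * length
        # per-fish terms
        wref = par[P_CONDITION_REF_A] * length**3
        floor_w = par[P_WEIGHT_FLOOR_FRAC] * wref
        cm = cmax(weight, temp, par)
        rest = par[P_MET_A] * weight**0.8 * math.exp(par[P_MET_T_COEF] * temp)
        vmax = par[P_MAX_SWIM_LENGTHS] * length / 100.0
        v_width = par[P_CAPTURE_V_WIDTH_FRAC] * vmax + 1e-9
        cap_area = par[P_CAPTURE_AREA_COEF] * (length / 100.0) ** 2
        s_terr_len = _sigmoid(
            (length - par[P_TERR_LEN_HALF]) / par[P_TERR_LEN_WIDTH]
        )
        s_pisc = 1.0
        if larger:
            s_pisc = 1.0 - par[P_PISC_RISK_MAX] * _sigmoid(
                (par[P_PISC_LEN_HALF] - length) / par[P_PISC_LEN_WIDTH]
            )
        search_pot = par[P_SEARCH_RATE_A] * weight**0.8
        if search_pot > cm:
            search_pot = cm
        met_search = rest * (1.0 + par[P_SEARCH_ACT])

        best_f = -1.0
        best_c = -1
        best_m = DRIFT
        best_dw = 0.0
        best_intake = 0.0
        if any_wet:
            for c in range(nc):
                if not wetted[c]:
                    continue
                s_base = (1.0 - terr_cell[c] * s_terr_len) * s_pisc * s_temp
                for m in range(2):
                    if m == DRIFT:
                        intake = drift_base[c] * cap_area * _sigmoid(
                            (vmax - velocity[c]) / v_width
                        ) * s_turb
                        if intake > cm:
                            intake = cm
                        if intake > drift_food[c]:
                            intake = drift_food[c]
                        rel = velocity[c] / vmax
                        if rel > 3.0:
                            rel = 3.0
                        met = rest * (1.0 + par[P_ACT_COST] * rel * (
                            1.0 - par[P_SHELTER_ACT_REDUCTION] * shelter[c]
                        ))
                    else:
                        intake = search_pot
                        if intake > search_food[c]:
                            intake = search_food[c]
                        met = met_search
                    if intake < 0.0:
                        intake = 0.0
                    dw = (intake * par[P_E_FOOD] - met) / e_t
                    wproj = weight + horizon * dw
                    if wproj < floor_w:
                        wproj = floor_w
                    kproj = wproj / wref
                    p = s_base * _sigmoid(
                        (kproj - par[P_STARV_K_HALF]) / par[P_STARV_K_WIDTH]
                    )
                    cond_term = kproj if kproj < 1.0 else 1.0
                    f = p**horizon * cond_term
                    if f < par[P_FITNESS_EPS]:
                        f = par[P_FITNESS_EPS]
                    if f > best_f:
                        best_f = f
                        best_c = c
                        best_m = m
                        best_dw = dw
                        best_intake = intake
        else:
            best_c = deepest
            best_m = SEARCH
            best_dw = -met_search / e_t
            best_intake = 0.0
        # claim food
        if best_intake > 0.0:
            if best_m == DRIFT:
                drift_food[best_c] -= best_intake
                if drift_food[best_c] < 0.0:
                    drift_food[best_c] = 0.0
            else:
                search_food[best_c] -= best_intake
                if search_food[best_c] < 0.0:
                    search_food[best_c] = 0.0
        # growth with starvation floor
        new_w = weight + best_dw
        if new_w < floor_w:
            new_w = floor_w
        # post-growth survival at the chosen cell (length updated when
        # condition exceeds 1, mirroring the growth rule)
        new_len = length
        s_terr_new = s_terr_len
        s_pisc_new = s_pisc
        if new_w > wref:
            new_len = (new_w / par[P_CONDITION_REF_A]) ** (1.0 / 3.0)
            s_terr_new = _sigmoid(
                (new_len - par[P_TERR_LEN_HALF]) / par[P_TERR_LEN_WIDTH]
            )
            if larger:
                s_pisc_new = 1.0 - par[P_PISC_RISK_MAX] * _sigmoid(
                    (par[P_PISC_LEN_HALF] - new_len) / par[P_PISC_LEN_WIDTH]
                )
        k_new = new_w / (par[P_CONDITION_REF_A] * new_len**3)
        p_out = (1.0 - terr_cell[best_c] * s_terr_new) * s_pisc_new * s_temp
        p_out *= _sigmoid(
            (k_new - par[P_STARV_K_HALF]) / par[P_STARV_K_WIDTH]
        )
        if not wetted[best_c]:
            p_out *= par[P_STRAND_SURV]
        out_cell[i] = best_c
        out_mode[i] = best_m
        out_dw[i] = new_w - weight
        out_intake[i] = best_intake
        out_psurv[i] = p_out
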