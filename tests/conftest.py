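import numpy as np
import pandas as pd
import pytest

from troutsim import environment as env
from troutsim.environment import Cell, ReachGeometry
from troutsim.ibm import IbmParams


@pytest.fixture(scope="session")
def gus_params():
    return env.get_preset("gus")


@pytest.fixture(scope="session")
def reach(gus_params):
    return env.generate_reach(gus_params, seed=7)


@pytest.fixture(scope="session")
def regime_5y(gus_params):
    return env.generate_daily_regime(gus_params, 5, seed=1)


@pytest.fixture
def ibm_params():
    return IbmParams()


@pytest.fixture
def tiny_reach():
    """Three hand-built cells: a deep slow pool, a fast riffle, a gravel run."""
    cells = (
        Cell(cell_id=0, area=20.0, ref_depth=0.5, ref_velocity=0.08,
             depth_exponent=0.4, velocity_exponent=0.4, shelter_fraction=0.3,
             gravel_fraction=0.0, dist_cover=1.0),
        Cell(cell_id=1, area=15.0, ref_depth=0.12, ref_velocity=0.45,
             depth_exponent=0.4, velocity_exponent=0.4, shelter_fraction=0.1,
             gravel_fraction=0.0, dist_cover=6.0),
        Cell(cell_id=2, area=18.0, ref_depth=0.25, ref_velocity=0.2,
             depth_exponent=0.4, velocity_exponent=0.4, shelter_fraction=0.2,
             gravel_fraction=0.3, dist_cover=3.0),
    )
    return ReachGeometry(cells=cells, reach_length=21.0, ref_flow=0.08)


@pytest.fixture
def immortal_params():
    """Parameters that force every survival probability to exactly 1."""
    return IbmParams(
        terr_risk_max=0.0, pisc_risk_max=0.0, starv_k_half=-10.0,
        temp_surv_half=1000.0, strand_surv=1.0,
    )


def constant_regime(n_days, flow=0.08, temp=10.0, turb=0.0,
                    start="2007-01-01"):
    dates = pd.date_range(start, periods=n_days + n_days // 90 + 2, freq="D")
    dates = dates[~((dates.month == 2) & (dates.day == 29))][:n_days]
    return pd.DataFrame(
        {"date": dates, "flow_m3s": flow, "temp_c": temp,
         "turbidity_ntu": turb}
    )


@pytest.fixture
def make_constant_regime():
    return constant_regime
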