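import numpy as np
import pandas as pd
import pytest

from illfit import CloneSpec, ExperimentDesign, default_clone_specs
from illfit.records import RECORD_COLUMNS


def make_records(rows):
    """Build a records table from compact row dicts (missing fields -> NaN)."""
    full = []
    for row in rows:
        base = {
            "clone_id": "A",
            "concentration_mgC_per_L": 1.0,
            "initial_mass_ug": 5.0,
            "final_mass_ug": np.nan,
            "age_first_repro_d": np.nan,
            "clutch_size": np.nan,
            "survived": False,
        }
        base.update(row)
        full.append(base)
    return pd.DataFrame(full, columns=RECORD_COLUMNS)


def survivor(clone="A", conc=1.0, m0=5.0, mt=40.0, age=8.0, clutch=10.0):
    return {"clone_id": clone, "concentration_mgC_per_L": conc,
            "initial_mass_ug": m0, "final_mass_ug": mt,
            "age_first_repro_d": age, "clutch_size": clutch, "survived": True}


@pytest.fixture
def single_clone_spec():
    return CloneSpec("A", g_intercept=-0.008, g_slope=1.16, g_breakpoint=0.7,
                     survival_prob=1.0, g_noise_sd=0.03)


@pytest.fixture
def small_design():
    return ExperimentDesign(seed=7)


@pytest.fixture
def four_clone_specs():
    return default_clone_specs()
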