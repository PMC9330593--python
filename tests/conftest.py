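import numpy as np
import pytest

from pr10flex.constants import BACKBONE_N_CYCLES, BACKBONE_RELAX_TIME
from pr10flex.dispersion import curves_from_table
from pr10flex.synthetic import (
    backbone_schedule,
    simulate_dispersion_dataset,
    truth_presets,
)


@pytest.fixture(scope="session")
def sched():
    return backbone_schedule()


@pytest.fixture(scope="session")
def backbone_nus():
    return np.array(BACKBONE_N_CYCLES) / BACKBONE_RELAX_TIME


@pytest.fixture(scope="session")
def helix_truth():
    return truth_presets("arah8_helix", seed=11)


@pytest.fixture(scope="session")
def sheet_truth():
    return truth_presets("arah8_sheet", seed=12)


@pytest.fixture(scope="session")
def helix_curves_noiseless(helix_truth, sched):
    tab = simulate_dispersion_dataset(helix_truth, sched, noise_sigma=0.0, seed=1)
    return curves_from_table(tab, sched.relax_time)


@pytest.fixture(scope="session")
def helix_curves_noisy(helix_truth, sched):
    tab = simulate_dispersion_dataset(helix_truth, sched, noise_sigma=0.3, seed=2)
    return curves_from_table(tab, sched.relax_time)
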