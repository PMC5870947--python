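import numpy as np
import pytest

from ckdcea.calibration import SolverOptions, calibrate, make_targets
from ckdcea.model_core import Subpopulation, TransitionModel, build_state_space
from ckdcea.synthetic import make_synthetic_inputs


@pytest.fixture(scope="session")
def truth():
    return make_synthetic_inputs(seed=11)


@pytest.fixture(scope="session")
def space(truth):
    return truth.space


@pytest.fixture(scope="session")
def sub():
    return Subpopulation(
        age_band="65-74", sex="female", race="white", baseline_egfr=45, uacr=300
    )


@pytest.fixture(scope="session")
def usual_fit(truth, sub):
    """Calibrated usual-care model for the default stratum (reused across tests)."""
    targets = make_targets(sub, truth.risk_inputs, truth.space)
    return calibrate(
        sub, targets, truth.space, truth.risk_inputs.life_table, SolverOptions(seed=7)
    )


def constant_transition_model(
    space,
    age_min=70,
    p_progress=0.0,
    p_esrd=0.0,
    p_death=0.0,
    p_death_esrd=0.0,
    n_ages=60,
):
    """Age-constant transition model on an arbitrary state space (test helper)."""
    nb = space.n_bins
    pp = np.full((n_ages, nb), float(p_progress))
    pp[:, -1] = 0.0
    pe = np.zeros((n_ages, nb))
    for i, lo in enumerate(space.bin_lowers):
        if lo in space.esrd_eligible:
            pe[:, i] = p_esrd
    pd = np.zeros((n_ages, space.n_states))
    pd[:, :nb] = p_death
    pd[:, space.esrd_index] = p_death_esrd
    return TransitionModel(space=space, age_min=age_min, p_progress=pp, p_esrd=pe, p_death=pd)


@pytest.fixture
def toy_space():
    """Tiny 4-state space: bins [10,14] and [5,9] (both ESRD-eligible) + ESRD + Death."""
    return build_state_space(top_egfr=14, floor_egfr=5)
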