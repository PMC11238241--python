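import numpy as np
import pytest
from hypothesis import settings

from vplkit import GroupDesign, ObserverParams

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def static_observer():
    """Non-learning, lapse-free observer: threshold fixed at 0.3 forever."""
    return ObserverParams("static", "g", c0=0.3, rho=0.0, lapse=0.0)


@pytest.fixture
def small_design():
    """Down-scaled two-group design for fast structural pipeline tests."""
    return GroupDesign(
        groups=("stim", "sham"),
        n_per_group=2,
        rho_by_group={"stim": (0.30, 0.0), "sham": (0.15, 0.0)},
        blocks_per_training_session=2,
        trials_per_block=60,
        trials_per_test=90,
    )
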