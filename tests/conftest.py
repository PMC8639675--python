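import numpy as np
import pytest

from arithmeeg.stimuli import load_problem_set
from arithmeeg.synthdata import SimulationConfig, simulate_participant


@pytest.fixture(scope="session")
def problems():
    return load_problem_set()


@pytest.fixture(scope="session")
def blink_sim(problems):
    """One full-length (80-trial) participant with generator ground truth.

    Shared by the ICA cleanup tests (preprocessing unit tests and the
    ocular-cleanup acceptance check).  The full session length matters:
    ICA's temporal separation accuracy — and with it the achievable blink
    suppression — grows with the amount of fitting data.
    """
    cfg = SimulationConfig(seed=5)
    part = simulate_participant(cfg, problems, 0, return_ground_truth=True)
    return cfg, part


@pytest.fixture(scope="session")
def blink_cleaned(blink_sim):
    """The blink fixture after the full cleaning recipe (computed once)."""
    from arithmeeg.preproc import preprocess

    _, part = blink_sim
    cleaned, report = preprocess(part.recording)
    return part, cleaned, report


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
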