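import numpy as np
import pytest

from thermarm.benchmark import study_config
from thermarm.protocol import MuscleClass, SessionProtocol
from thermarm.simulate import simulate_session


@pytest.fixture(scope="session")
def biceps_protocol() -> SessionProtocol:
    """The multi-muscle study protocol: 3 sets x 12 reps, 92 s recovery."""
    return SessionProtocol(target_muscle=MuscleClass.BICEPS, arm_side="left")


@pytest.fixture(scope="session")
def noiseless_recording(biceps_protocol):
    """One noiseless simulated biceps session on small frames."""
    cfg = study_config(MuscleClass.BICEPS, seed=0, noise_sd=0.0)
    return simulate_session(biceps_protocol, cfg)


@pytest.fixture(scope="session")
def noiseless_heatmaps(noiseless_recording):
    from thermarm.heatmap import select_set_heatmaps

    return select_set_heatmaps(noiseless_recording)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
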