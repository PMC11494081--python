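import numpy as np
import pytest

import spurdyn as sd
from spurdyn.transport import SimulationConfig, run_ensemble


@pytest.fixture(scope="session")
def bundle():
    """Default in-memory cross-section bundle (built once per session)."""
    return sd.default_bundle()


@pytest.fixture(scope="session")
def warm_engine(bundle):
    """Compile the stepping kernel once so timings reflect physics only."""
    run_ensemble(
        SimulationConfig(deposition_energy=5.0, n_trials=1, cutoff_time=0.01, seed=0),
        bundle,
    )
    return True


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
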