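import numpy as np
import pytest

import gaitfuse as gf


@pytest.fixture(scope="session")
def short_session() -> gf.SyntheticSession:
    """One 60 s synthetic walking session shared by fast unit tests."""
    return gf.simulate_session(gf.GaitCycleParams(duration=60.0), seed=42)


@pytest.fixture(scope="session")
def jitter_free_params() -> gf.GaitCycleParams:
    return gf.GaitCycleParams(
        cycle_duration=1.0, cycle_jitter_sd=0.0, stance_fraction=0.6,
        leg_phase_offset=0.5, duration=10.0, sampling_rate=1000.0,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
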