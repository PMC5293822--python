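import numpy as np
import pytest

import limbdecode as ld


@pytest.fixture(scope="session")
def small_session() -> ld.SyntheticSession:
    """One small dataset shared across test modules (8 trials, 12 units)."""
    return ld.make_session(ld.SessionConfig(n_trials=8, n_units=12), seed=11)


@pytest.fixture(scope="session")
def fac_session() -> ld.SyntheticSession:
    """Dataset with grouped spike-locked EMG facilitation injected."""
    return ld.make_session(
        ld.SessionConfig(n_trials=10, n_units=32), seed=21, facilitation="grouped"
    )


@pytest.fixture(scope="session")
def preprocessed(small_session) -> ld.PreprocessedSession:
    return ld.preprocess_session(small_session)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
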