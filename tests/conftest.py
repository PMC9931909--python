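import numpy as np
import pytest

from wcplast import ModelParams, RunSettings


@pytest.fixture(scope="session")
def params() -> ModelParams:
    """Default constants with the 12-Hz-labelled time-constant pair."""
    return ModelParams.for_resonance(12)


@pytest.fixture()
def short_settings() -> RunSettings:
    """A cheap two-unit run for bookkeeping and determinism checks."""
    return RunSettings(
        n_steps=5_000, n_discard=1_000, z=0.0015,
        record_activity_every=1, record_weights_every=10,
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
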