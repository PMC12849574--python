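import numpy as np
import pytest

from swarmkin import SwarmScenario, generate_replicate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scenario():
    """A fast-to-generate replicate: few, short (but >25 s) tracks."""
    return SwarmScenario(
        group_code=100,
        n_swarming_tracks=6,
        speed_mean=0.70,
        track_duration_range=(27.0, 32.0),
        n_noise_tracks=3,
    )


@pytest.fixture(scope="session")
def small_replicate(small_scenario):
    tracks, truth = generate_replicate(small_scenario, seed=7, replicate_id="rA")
    return tracks, truth
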