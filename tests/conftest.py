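"""Shared fixtures: synthetic sessions reused across test modules."""

import numpy as np
import pytest

from ssveplab.preprocess import (filter_recording, restrict_channels,
                                 segment_trials)
from ssveplab.simulate import (POSTERIOR_CHANNELS, SimulationConfig,
                               generate_session)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def default_session(default_config):
    """40-trial session under the default (high stimulus SNR) conditions."""
    return generate_session(default_config, 10, seed=1)


@pytest.fixture(scope="session")
def default_segments(default_session):
    """Filtered, segmented, posterior-channel trials of the default session."""
    filtered = filter_recording(default_session)
    segments = segment_trials(filtered, stimulation_length_s=5.0)
    return restrict_channels(segments, POSTERIOR_CHANNELS)


@pytest.fixture(scope="session")
def candidate_frequencies(default_config):
    return sorted(default_config.target_frequencies)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
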