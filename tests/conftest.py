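"""Shared fixtures: the two-part frame schedule and a noise-free input
function generated once per session (they are deterministic)."""

import numpy as np
import pytest

from petquant.invasive import default_frame_weights
from petquant.synthetic import InputProfile, default_frame_schedule, generate_input_profile


@pytest.fixture(scope="session")
def schedule():
    return default_frame_schedule()


@pytest.fixture(scope="session")
def profile():
    return InputProfile()


@pytest.fixture(scope="session")
def true_input(profile, schedule):
    """(Cwb array, InputFunction) on a 0.05-min grid covering the schedule."""
    grid = np.arange(0.0, schedule.ends_min[-1] + 0.025, 0.05)
    return generate_input_profile(profile, grid)


@pytest.fixture(scope="session")
def aif(true_input):
    return true_input[1]


@pytest.fixture(scope="session")
def weights(schedule):
    return default_frame_weights(schedule)
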