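import numpy as np
import pytest

from adlsim import (
    FIG2_STYLE_PLACE_TYPES,
    generate_fixture_layout,
    generate_schedule,
    sample_profile,
)


@pytest.fixture(scope="session")
def full_layout():
    """A house containing one instance of every physical place type."""
    return generate_fixture_layout(1)


@pytest.fixture(scope="session")
def sparse_layout():
    """A house lacking the writing desk and washing machine."""
    return generate_fixture_layout(1, include=FIG2_STYLE_PLACE_TYPES)


@pytest.fixture(scope="session")
def default_profile():
    return sample_profile(1)


@pytest.fixture(scope="session")
def sixty_day_run(full_layout):
    """Canonical long-horizon simulation with a sampled default profile."""
    return generate_schedule(full_layout, 60 * 24.0, seed=1)


@pytest.fixture(scope="session")
def sparse_run(sparse_layout):
    """Ten simulated days in the desk/washing-machine-free house, MV history kept."""
    return generate_schedule(sparse_layout, 10 * 24.0, seed=1, track_mv=True)
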