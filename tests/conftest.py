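import numpy as np
import pytest

import domealign as da


@pytest.fixture(scope="session")
def default_scenario():
    """Default doming scenario: 41 images, 40 markers, noise 0.5 px."""
    return da.DomingScenario(seed=2024)


@pytest.fixture(scope="session")
def default_tracks(default_scenario):
    return da.simulate_tracks(default_scenario)


@pytest.fixture(scope="session")
def default_sol1(default_tracks):
    tracks, truth = default_tracks
    return da.standard_align(tracks, truth.geometry)


@pytest.fixture(scope="session")
def default_sol2(default_tracks, default_sol1):
    tracks, _truth = default_tracks
    return da.fit_motion(default_sol1, tracks)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
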