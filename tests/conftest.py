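"""Shared fixtures: one full synthetic bundle per session plus variants."""

import warnings

import pytest

from azadem import synthetic_data as sd


@pytest.fixture(scope="session")
def bundle():
    """Default full fixture bundle (with genome sequence), seed 7."""
    return sd.generate(sd.SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def tracks(bundle):
    return bundle.angle_tracks()


@pytest.fixture(scope="session")
def light_bundle():
    """Sequence-free bundle for track-level analyses (same tables as full)."""
    return sd.generate(sd.SimulationConfig(seed=7), include_sequence=False)


@pytest.fixture(scope="session")
def null_bundle():
    """Zero-effect bundle: no demethylation planted at any dose."""
    cfg = sd.SimulationConfig(seed=11, demeth_effect={0.25: (0.0, 0.0), 1.0: (0.0, 0.0)})
    return sd.generate(cfg, include_sequence=False)


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Silence the under-determined-SOM warning that small fixtures trigger."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="only .* training vectors")
        yield
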