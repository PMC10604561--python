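"""Shared fixtures: a pre-trained valence model, freshly trained models,
and default simulated recordings."""

from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import thermoaffect as ta

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

FIXTURES = Path(__file__).parent / "fixtures"


@pytest.fixture(scope="session")
def fixture_model() -> ta.ValenceModel:
    """The checked-in pre-trained valence model (reproducible classification)."""
    return ta.ValenceModel.load(FIXTURES / "valence_model.json")


@pytest.fixture(scope="session")
def trained_model() -> ta.ValenceModel:
    """A valence model trained in-session on simulator windows."""
    return ta.train_default_model(seed=101, n_per_class=400)


@pytest.fixture(scope="session")
def default_recording():
    """One default-condition recording with ground truth."""
    config = ta.SimConfig(seed=5, duration=300.0)
    return ta.simulate_recording(config)


def constant_series(value: float, duration: float, fs: float = 10.0, roi: str = "roi"):
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    return ta.ThermalTimeSeries(t, np.full(n, value), np.zeros(n, bool), roi_name=roi)
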