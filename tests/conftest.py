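"""Shared fixtures.

Expensive simulation runs are session-scoped and reused across test
modules; everything is generated programmatically (no stored data).
"""

import numpy as np
import pytest

import thermoseed as ts
from thermoseed.pipeline import run_simulation


@pytest.fixture(scope="session")
def default_scene():
    return ts.default_scene()


@pytest.fixture(scope="session")
def fast_scene():
    """Reference geometry with a short 60 s exposure for structural tests."""
    exposure = ts.ExposureConfig(duration=60.0, field_off_time=60.0)
    return ts.default_scene(exposure=exposure)


@pytest.fixture(scope="session")
def centered_result(default_scene):
    """One full centred reference run (2 mm, 900 s, noiseless probes)."""
    return run_simulation(default_scene, resolution=2e-3, noise_sd=0.0)


@pytest.fixture(scope="session")
def air_result():
    """Bare scaffold heated in air (IR-camera style setup), 600 s."""
    scene = ts.default_scene("air")
    return run_simulation(scene, resolution=2e-3, noise_sd=0.0, duration=600.0)
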