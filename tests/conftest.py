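"""Shared fixtures: all scenes are generated programmatically, never stored."""

import numpy as np
import pytest

from azmetrics import (SceneConfig, generate_activated_scene,
                       generate_resting_scene)


@pytest.fixture(scope="session")
def default_config() -> SceneConfig:
    return SceneConfig(seed=1)


@pytest.fixture(scope="session")
def resting_scene(default_config):
    return generate_resting_scene(default_config)


@pytest.fixture(scope="session")
def small_resting_scene():
    """A shorter band (fewer vesicles) for the more expensive geometry tests."""
    return generate_resting_scene(SceneConfig(seed=3, band_length=300.0))


@pytest.fixture(scope="session")
def activated_scene():
    return generate_activated_scene(SceneConfig(seed=7))


@pytest.fixture(scope="session")
def resting_pool():
    """30 seeded resting scenes for pooled parameter-recovery checks."""
    return [generate_resting_scene(SceneConfig(seed=s)) for s in range(30)]


@pytest.fixture(scope="session")
def activated_pool():
    """12 seeded activated scenes (>=20 undocked vesicles per distance bin)."""
    return [generate_activated_scene(SceneConfig(seed=1000 + s))
            for s in range(12)]


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
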