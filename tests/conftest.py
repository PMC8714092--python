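import numpy as np
import pytest
from hypothesis import settings

from patchforage import (
    ForagingConfig,
    ObservableSpec,
    environment_variants,
    optimize_policy,
)
from patchforage.gaze_processing import TaskGeometry

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config():
    return ForagingConfig()


@pytest.fixture(scope="session")
def geometry():
    return TaskGeometry()


@pytest.fixture(scope="session")
def solved_default(default_config):
    """Fully observable solve of the reference (variant A) configuration."""
    return optimize_policy(default_config)


@pytest.fixture(scope="session")
def solved_all_policies(default_config):
    """All four observability settings solved on the reference config."""
    return {name: optimize_policy(default_config,
                                  ObservableSpec.from_name(name))
            for name in ("P1", "P2", "P3", "P4")}


@pytest.fixture(scope="session")
def toy_config():
    """Two environments, two objects, binary reward sizes: small enough for
    exhaustive policy enumeration."""
    point_mass = ((1.0, 0.0, 0.0, 0.0, 0.0),) * 2
    return ForagingConfig(n_envs=2, n_objects=2, p_max=(0.3, 0.8),
                          tau=(0.5, 0.5), size_dist=point_mass)
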