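import numpy as np
import pytest

import hemotrace as ht


@pytest.fixture(scope="session")
def props():
    return ht.BloodProperties()


@pytest.fixture(scope="session")
def env():
    return ht.AirEnvironment()


@pytest.fixture(scope="session")
def frame():
    return ht.default_wall_frame()


@pytest.fixture(scope="session")
def cfg():
    return ht.SceneConfig()


@pytest.fixture(scope="session")
def simulated_pattern():
    """One noise-free synthetic impact pattern with its ground truth."""
    source = ht.SourceModel(seed=11, n_droplets=40)
    stains, truth = ht.simulate_pattern(source)
    return source, stains, truth


def make_line_trajectory(point_cm, direction, stain_id=None):
    """Straight Trajectory through a point (cm) along a direction (any norm)."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    a_m = np.asarray(point_cm, dtype=float) / 100.0
    return ht.Trajectory(
        model="straight",
        times=np.array([0.0, 1.0]),
        positions=np.vstack([a_m, a_m + d]),
        velocities=np.zeros((2, 3)),
        diameter=1e-3,
        stain_id=stain_id,
        line_point=a_m,
        line_dir=d,
    )
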