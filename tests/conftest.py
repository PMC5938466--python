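import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import articulate3d as a3

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture(scope="session")
def single_set():
    """Noise-free single-articulation synthetic sample."""
    return a3.make_articulated_pair(
        n_specimens=10, n_landmarks=(8, 10), joint_type="single", seed=11
    )


@pytest.fixture(scope="session")
def double_set():
    """Noise-free double-articulation synthetic sample."""
    return a3.make_articulated_pair(
        n_specimens=10, n_landmarks=(8, 10), joint_type="double", seed=12
    )


def translated_pair(sset):
    """Translate each structure by its articulation (first role) landmark."""
    return a3.StructurePair(
        a3.translate(sset.data_1, sset.roles_1[0]),
        a3.translate(sset.data_2, sset.roles_2[0]),
    )


@pytest.fixture(scope="session")
def single_pair(single_set):
    return translated_pair(single_set)


@pytest.fixture(scope="session")
def double_pair(double_set):
    return translated_pair(double_set)


def pairwise_distances(points):
    pts = np.asarray(points)
    return np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)


def signed_volumes(points, quadruples):
    """Signed tetrahedron volumes (x6) for the given landmark quadruples."""
    pts = np.asarray(points)
    out = []
    for (a, b, c, d) in quadruples:
        m = np.stack([pts[b] - pts[a], pts[c] - pts[a], pts[d] - pts[a]])
        out.append(np.linalg.det(m))
    return np.array(out)
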