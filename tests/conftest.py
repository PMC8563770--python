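import numpy as np
import pytest
import trimesh
from hypothesis import HealthCheck, settings

from maskfit import sizing, synthetic

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def medium_face():
    """Noiseless synthetic face at the catalogue's Medium (II) parameters."""
    spec = synthetic.FaceSpec(
        eye_to_chin=104.9, A=24.4, sigma=10.2, ridge_angle=25.0, seed=0
    )
    return (*synthetic.synth_face(spec), spec)


@pytest.fixture(scope="session")
def ref_table():
    return sizing.reference_table()


@pytest.fixture(scope="session")
def default_cohort():
    return synthetic.synth_cohort(synthetic.CohortSpec(n=10_000, seed=11))


@pytest.fixture()
def tetrahedron():
    """Unit tetrahedron as raw (vertices, faces) arrays."""
    v = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )
    f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return trimesh.Trimesh(vertices=v, faces=f, process=False)
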