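import numpy as np
import pytest
import trimesh

from arthroshape import SurfaceMesh


def sphere_mesh(radius: float = 1.0, subdivisions: int = 3,
                center=(0.0, 0.0, 0.0)) -> SurfaceMesh:
    tm = trimesh.creation.icosphere(subdivisions)
    return SurfaceMesh(tm.vertices * radius + np.asarray(center), tm.faces)


def ellipsoid_mesh(axes=(10.0, 7.0, 5.0), subdivisions: int = 3) -> SurfaceMesh:
    tm = trimesh.creation.icosphere(subdivisions)
    return SurfaceMesh(tm.vertices * np.asarray(axes), tm.faces)


@pytest.fixture(scope="session")
def unit_sphere_fine() -> SurfaceMesh:
    """Unit icosphere with 5120 faces (interior-accuracy fixture)."""
    return sphere_mesh(1.0, 4)


@pytest.fixture(scope="session")
def ellipsoid() -> SurfaceMesh:
    """Asymmetric closed mesh: unambiguous pose for registration tests."""
    return ellipsoid_mesh()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
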