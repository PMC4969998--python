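import numpy as np
import pytest

from phytomesh import (
    RibbonSpec,
    SphereSpec,
    primitive,
    twisted_ribbon,
    uv_sphere,
)


@pytest.fixture(scope="session")
def sphere2():
    """The 50 mm validation sphere at 2° angular resolution."""
    return uv_sphere(SphereSpec(radius=50.0, resolution_deg=2.0))


@pytest.fixture(scope="session")
def sphere4():
    return uv_sphere(SphereSpec(radius=50.0, resolution_deg=4.0))


@pytest.fixture(scope="session")
def sphere8():
    return uv_sphere(SphereSpec(radius=50.0, resolution_deg=8.0))


@pytest.fixture(scope="session")
def sphere30():
    return uv_sphere(SphereSpec(radius=50.0, resolution_deg=30.0))


@pytest.fixture()
def cube():
    return primitive("cube")


@pytest.fixture()
def tetra():
    return primitive("tetrahedron", 2.0)


STRIP_SPEC = RibbonSpec(length=180.0, width=30.0, twist_turns=0.0,
                        n_length=181, n_width=31)


@pytest.fixture(scope="session")
def strip():
    """Flat 180 × 30 mm strip at 1 mm resolution."""
    return twisted_ribbon(STRIP_SPEC)


def strip_vertex(i: int, j: int, n_width: int = 31) -> int:
    """Vertex index in the ribbon's row-major (length, width) grid."""
    return i * n_width + j


@pytest.fixture()
def rng():
    return np.random.default_rng(20160924)
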