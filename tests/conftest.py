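import pytest

from eitlung.forward import CEMSystem, ConductivityField
from eitlung.mesh import build_thorax_mesh
from eitlung.phantom import generate_cohort
from eitlung.reconstruct import Rasterizer


@pytest.fixture(scope="session")
def mesh400():
    return build_thorax_mesh("circle", 400)


@pytest.fixture(scope="session")
def system400(mesh400):
    return CEMSystem(mesh400)


@pytest.fixture(scope="session")
def J400(system400, mesh400):
    return system400.jacobian(ConductivityField.homogeneous(mesh400))


@pytest.fixture(scope="session")
def raster400(mesh400):
    return Rasterizer(mesh400)


@pytest.fixture(scope="session")
def mesh200():
    return build_thorax_mesh("circle", 200)


@pytest.fixture(scope="session")
def system200(mesh200):
    return CEMSystem(mesh200)


@pytest.fixture(scope="session")
def subject():
    return generate_cohort(1, seed=3)[0]
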