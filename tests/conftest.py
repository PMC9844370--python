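import pytest

import durernet as dn
from durernet.analysis import descriptor_table


@pytest.fixture(scope="session")
def solids():
    return {name: dn.build_platonic(name) for name in dn.PLATONIC_NAMES}


@pytest.fixture(scope="session")
def tetrahedron(solids):
    return solids["tetrahedron"]


@pytest.fixture(scope="session")
def cube(solids):
    return solids["cube"]


@pytest.fixture(scope="session")
def octahedron(solids):
    return solids["octahedron"]


@pytest.fixture(scope="session")
def dodecahedron(solids):
    return solids["dodecahedron"]


@pytest.fixture(scope="session")
def icosahedron(solids):
    return solids["icosahedron"]


@pytest.fixture(scope="session")
def cube_census(cube):
    return dn.net_census(cube)


@pytest.fixture(scope="session")
def octa_census(octahedron):
    return dn.net_census(octahedron)


# The two large solids take ~5.18M spanning trees each; computed once per
# session and shared by every test that needs the full enumeration.


@pytest.fixture(scope="session")
def dodeca_census(dodecahedron):
    return dn.net_census(dodecahedron)


@pytest.fixture(scope="session")
def icosa_census(icosahedron):
    return dn.net_census(icosahedron)


@pytest.fixture(scope="session")
def cube_nets(cube, cube_census):
    return list(dn.enumerate_nets(cube, cube_census))


@pytest.fixture(scope="session")
def octa_nets(octahedron, octa_census):
    return list(dn.enumerate_nets(octahedron, octa_census))


@pytest.fixture(scope="session")
def dodeca_table(dodecahedron, dodeca_census):
    return descriptor_table(dodecahedron, dodeca_census)
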