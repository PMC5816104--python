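import numpy as np
import pytest

from spincube.geometry import Atom, Structure, partition_structure
from spincube.fixtures import CubaneSpec, make_cubane, make_lip_a_fixture, packaged_tables


@pytest.fixture(scope="session")
def table1_and_profiles():
    return packaged_tables()


@pytest.fixture(scope="session")
def table1(table1_and_profiles):
    return table1_and_profiles[0]


@pytest.fixture(scope="session")
def profiles(table1_and_profiles):
    return table1_and_profiles[1]


@pytest.fixture()
def ideal_cubane():
    """Ideal cubane with 4 thiolate stubs, no jitter."""
    return make_cubane(CubaneSpec(), seed=0)


@pytest.fixture(scope="session")
def lipa_bundle():
    return make_lip_a_fixture(seed=11)


@pytest.fixture()
def chain10():
    """10 carbon atoms in a bonded chain (1.5 A spacing), serials 1..10."""
    atoms = [
        Atom("C", (1.5 * i, 0.0, 0.0), 0.1 * ((-1) ** i), i + 1) for i in range(10)
    ]
    return Structure(atoms, "chain")


def random_charged_structure(rng: np.random.Generator, n: int = 8) -> Structure:
    """Random geometry with random partial charges, atoms well separated."""
    pos = rng.uniform(0.0, 8.0, size=(n, 3))
    # push coincident-ish atoms apart to keep Coulomb well-behaved
    for i in range(1, n):
        while np.min(np.linalg.norm(pos[:i] - pos[i], axis=1)) < 0.8:
            pos[i] = rng.uniform(0.0, 8.0, size=3)
    elements = rng.choice(["C", "N", "O", "S", "H"], size=n)
    atoms = [
        Atom(str(e), tuple(p), float(rng.normal(0.0, 0.4)), i + 1)
        for i, (e, p) in enumerate(zip(elements, pos))
    ]
    return Structure(atoms, "random")


@pytest.fixture()
def make_random_structure():
    return random_charged_structure


def random_rigid_motion(rng: np.random.Generator):
    """A random proper rotation matrix and translation vector."""
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    t = rng.uniform(-20, 20, size=3)
    return q, t


@pytest.fixture()
def make_rigid_motion():
    return random_rigid_motion
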