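import numpy as np
import pytest

from tipcast import syslib as S


def make_system(a: dict, b: dict, name: str = "sys") -> S.PolySystem:
    """Polynomial system from sparse coefficient dicts on the monomial basis
    (1, x, y, x2, xy, y2, x3, x2y, xy2, y3)."""
    A = np.zeros(10)
    B = np.zeros(10)
    for k, v in a.items():
        A[k] = v
    for k, v in b.items():
        B[k] = v
    return S.PolySystem(A, B, id=name)


@pytest.fixture(scope="session")
def fold_nf():
    """Fold normal form dx = a1 - x^2, dy = -y (crossing at a1 = 0)."""
    return make_system({0: 1.0, 3: -1.0}, {2: -1.0}, "nf-fold")


@pytest.fixture(scope="session")
def transcritical_nf():
    """Transcritical normal form dx = a2 x - x^2, dy = -y (crossing at 0)."""
    return make_system({1: -1.0, 3: -1.0}, {2: -1.0}, "nf-transcritical")


@pytest.fixture(scope="session")
def hopf_nf():
    """Rotational Hopf normal form: dx = a2 x - y - x r^2, dy = x - y r^2."""
    return make_system({1: -1.0, 2: -1.0, 6: -1.0, 8: -1.0},
                       {1: 1.0, 7: -1.0, 9: -1.0}, "nf-hopf")


@pytest.fixture(scope="session")
def small_library():
    """A 9-record bifurcation library shared across tests."""
    return S.build_library(3, 3, 3, rng_seed=42)


@pytest.fixture(scope="session")
def small_corpus(small_library):
    """120 labeled training series from the shared library."""
    from tipcast import simulate as sim
    return sim.make_training_set(small_library, rng_seed=7, n_instances=120)
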