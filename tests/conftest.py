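import numpy as np
import pytest

from osteobeam.fixtures import generate_fixtures
from osteobeam.solver import OvercriticalAxialForceError, ScrewBeamModel

FIXTURE_SEED = 20260903


@pytest.fixture(scope="session")
def fixture_set():
    return generate_fixtures(FIXTURE_SEED)


@pytest.fixture
def ref_model():
    """Solid 4.5 mm steel screw, N = 0: the simplest well-behaved case."""
    return ScrewBeamModel(
        L=0.09, L1=0.03, L2=0.06, k=2.0e7, E=200e9, J_ZT=2.0128895898635385e-11,
        F1=287.0, N=0.0,
    )


def random_admissible_model(rng: np.random.Generator) -> ScrewBeamModel:
    """Sample a sub-critical beam model spanning the admissible ranges."""
    while True:
        D = rng.uniform(3.0e-3, 6.5e-3)
        J = np.pi * D**4 / 64.0
        E = rng.choice([110e9, 200e9])
        L = rng.uniform(0.060, 0.120)
        u1 = rng.uniform(0.15, 0.45)
        u2 = rng.uniform(u1 + 0.15, 0.90)
        k = 10.0 ** rng.uniform(6.0, 9.0)
        F1 = rng.uniform(100.0, 1200.0)
        N = -rng.uniform(0.0, 0.95) * np.sqrt(4.0 * E * J * k)
        try:
            return ScrewBeamModel(L=L, L1=u1 * L, L2=u2 * L, k=k, E=E, J_ZT=J, F1=F1, N=N)
        except (OvercriticalAxialForceError, ValueError):  # pragma: no cover
            continue
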