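import numpy as np
import pytest

from cation3pi import (
    BoxParameters,
    SurrogateBackend,
    SurrogateParameters,
    SyntheticSpec,
    build_triangular_box,
    gen_complex_suite,
    make_pair,
)
from cation3pi.synthetic import build_site_complex


@pytest.fixture(scope="session")
def na_box():
    """Gas-phase Na⁺⊗3Bz triangular box at the default centroid distance."""
    return build_triangular_box("Na", BoxParameters(2.6))


@pytest.fixture(scope="session")
def na_gas_pair(na_box):
    return make_pair(na_box)


@pytest.fixture(scope="session")
def na_bridge_pair():
    """Na⁺⊗3Bz-6W (two bridge waters per ring) and its frozen reduction."""
    return make_pair(build_site_complex("Na", "bridge"))


@pytest.fixture(scope="session")
def pairwise_backend():
    return SurrogateBackend(SurrogateParameters())


@pytest.fixture(scope="session")
def complex_suite():
    """The 12-complex synthetic inventory (3 cations x 4 hydration patterns)."""
    return gen_complex_suite(SyntheticSpec(seed=0))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random proper rotation matrix via QR."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
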