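import numpy as np
import pytest

from polycollapse.energy import ChainSpec


@pytest.fixture
def chain600() -> ChainSpec:
    """The reference chain length used throughout: L* = 600."""
    return ChainSpec(600.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240716)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
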