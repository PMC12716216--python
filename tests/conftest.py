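import numpy as np
import pytest

from trespfret import PhotophysicsParams
from trespfret.fixtures import make_charge_set


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def photophysics():
    """Tryptophan-like donor: τ_D a few ns, R₀ tens of Å, n² = 2."""
    return PhotophysicsParams(
        tau_d=5.0, r0=30.0, n_refr=float(np.sqrt(2.0)), mu_d_mag=1.2, mu_a_mag=2.0
    )


@pytest.fixture
def charge_set():
    return make_charge_set(n_atoms=16, seed=7)


def random_rotation(rng):
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    return q * np.sign(np.diag(r))
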