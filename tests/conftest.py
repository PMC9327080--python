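import numpy as np
import pytest

from sehop import model as M


@pytest.fixture(scope="session")
def default_model():
    return M.default_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_random_model(rng, n_modes=2, n_singlets=2, n_triplets=0, coupling=0.05):
    """Small random LVC model with a valid (strictly lowest) ground state."""
    ns = n_singlets + n_triplets
    omega = rng.uniform(0.05, 0.2, n_modes)
    eps = np.sort(rng.uniform(0.5, 4.0, ns))
    eps[0] = 0.0
    kappa = rng.normal(0.0, 0.1, (ns, n_modes))
    lam = np.zeros((ns, ns, n_modes))
    for block in (range(n_singlets), range(n_singlets, ns)):
        block = list(block)
        for i in block:
            for j in block:
                if i < j:
                    val = rng.normal(0.0, coupling, n_modes)
                    lam[i, j] = lam[j, i] = val
    soc = (rng.normal(0, 0.003, (n_singlets, n_triplets, 3))
           + 1j * rng.normal(0, 0.003, (n_singlets, n_triplets, 3)))
    return M.VibronicModel(omega=omega, epsilon=eps, kappa=kappa, lam=lam,
                           soc_cart=soc, n_singlets=n_singlets,
                           n_triplets=n_triplets)


@pytest.fixture()
def random_model(rng):
    return make_random_model(rng)
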