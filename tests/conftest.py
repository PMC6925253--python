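import numpy as np
import pytest

from rockbundle.model import build_energy_model, build_toy_transporter


@pytest.fixture(scope="session")
def small_system():
    """Small toy transporter (2 helices per bundle) shared across tests."""
    structure, refs = build_toy_transporter(2, 10, 25.0, seed=1)
    return structure, refs


@pytest.fixture(scope="session")
def default_system():
    """Default-size toy transporter (4 helices per bundle)."""
    structure, refs = build_toy_transporter(4, 10, 25.0, seed=1)
    return structure, refs


@pytest.fixture(scope="session")
def default_models(default_system):
    structure, refs = default_system
    bound = build_energy_model(structure, refs, ion_present=True)
    return bound, bound.without_ion()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rotation(rng):
    """Uniform random proper rotation matrix."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
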