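import numpy as np
import pytest

from kinid.fixtures import make_model, proportional_r_fn
from kinid.models import NoiseModel, apply_noise, simulate


@pytest.fixture(scope="session")
def product_model():
    return make_model("product_ni")


@pytest.fixture(scope="session")
def mm_model():
    return make_model("mm_chain")


@pytest.fixture(scope="session")
def product_data():
    """Noisy product_ni series on its default grid (seed 0)."""
    m = make_model("product_ni")
    grid = np.linspace(0.1, 4.0, 40)
    clean = simulate(m, m.theta_true, grid)
    noisy = apply_noise(clean, NoiseModel(kind="multiplicative", c_mult=0.2, seed=0))
    return m, clean, noisy


@pytest.fixture(scope="session")
def prop_r_fn():
    return proportional_r_fn(0.2)


def R_from_rfn(r_fn, data):
    return [
        np.atleast_2d(r_fn(k, y)) @ np.atleast_2d(r_fn(k, y)).T
        for k, y in enumerate(data.values)
    ]
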