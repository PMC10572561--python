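import numpy as np
import pytest

from petgan.phantom import OrganSpec, PhantomSpec


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_spec():
    """A 6-slice 16x16 two-organ phantom with exactly known kinetics."""
    organs = [
        OrganSpec("liver", center=(7.0, 7.0), semi_axes=(4.0, 5.0),
                  slice_range=(1, 4), tac=[(1.2, 0.0), (1.4, 0.025)]),
        OrganSpec("bladder", center=(8.0, 8.0), semi_axes=(2.5, 2.5),
                  slice_range=(4, 6), tac=[(8.0, 0.0), (-8.0, 0.03)]),
    ]
    return PhantomSpec(n_slices=6, slice_shape=(16, 16), organs=organs,
                       background_activity=0.1, seed=5)


def numerical_gradient(f, x, eps=1e-6):
    """Central-difference gradient of a scalar function of an array."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = f(x)
        x[i] -= 2 * eps
        fm = f(x)
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g
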