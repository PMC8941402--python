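import numpy as np
import pytest

from hairfield import make_row_array, solve_equilibrium


@pytest.fixture(scope="session")
def unit_hair():
    """A single upright unit hair at the origin."""
    return make_row_array(1, K=1.0)


@pytest.fixture(scope="session")
def pair_delta10_K01():
    """Two identical unit hairs, spacing 10, weak coupling."""
    return make_row_array(2, delta=10.0, K=0.1)


@pytest.fixture(scope="session")
def pair_delta1_K1():
    """Two identical unit hairs, spacing 1, moderate coupling (reference case)."""
    return make_row_array(2, delta=1.0, K=1.0)


@pytest.fixture(scope="session")
def reference_field(pair_delta1_K1):
    """Deflection field of the reference two-hair case, q_p = 10."""
    from hairfield import deflection_field

    eq = solve_equilibrium(pair_delta1_K1)
    return deflection_field(pair_delta1_K1, 10.0, nx=301, ny=301, equilibrium=eq), eq


def random_config(rng, n_max=5):
    """A random small hair array with order-unity parameters."""
    N = int(rng.integers(2, n_max + 1))
    delta = float(rng.uniform(0.5, 5.0))
    lengths = rng.uniform(0.7, 1.3, size=N).tolist()
    charges = rng.uniform(0.5, 1.5, size=N).tolist()
    springs = rng.uniform(0.7, 1.3, size=N).tolist()
    K = float(10 ** rng.uniform(-2, 1))
    return make_row_array(N, delta=delta, lengths=lengths, charges=charges,
                          springs=springs, K=K)
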