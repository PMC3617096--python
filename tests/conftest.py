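import numpy as np
import pytest

from fpcatest import ExpressionMatrix, simulate_one_group
from fpcatest.simulate import basis_one_group


@pytest.fixture(scope="session")
def dense_grid():
    """Dense grid on the one-group interval, for quadrature-accurate checks."""
    return np.linspace(100.0, 305.0, 101)


@pytest.fixture(scope="session")
def large_one_group_sim():
    """5000 all-signal genes; shared by the Monte-Carlo covariance checks."""
    return simulate_one_group(n=5000, pi0=1.0, seed=424242)


@pytest.fixture(scope="session")
def rank3_surface(dense_grid):
    """Sum_l lambda_l phi_l phi_l^T with lambda = (4, 2, 1) on the dense grid."""
    phi = basis_one_group(dense_grid)
    lam = np.array([4.0, 2.0, 1.0])
    return (phi.T * lam) @ phi, phi, lam


def small_matrix():
    times = np.array([0.0, 1.0, 2.0, 3.0])
    values = np.array(
        [
            [5.0, 5.0, 5.0, 5.0],
            [1.0, 2.0, 3.0, 4.0],
            [1.0, np.nan, 3.0, 5.0],
        ]
    )
    return ExpressionMatrix(["a", "b", "c"], times, values)


@pytest.fixture
def tiny_expression():
    return small_matrix()
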