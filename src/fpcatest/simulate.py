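"""Synthetic time-course expression data with known differential labels.

Two generating models are provided, mirroring a yeast cell-cycle study
design.  Both write curves in a small orthonormal Fourier basis and add
i.i.d. Gaussian measurement noise with variance 0.01.

One-group model (non-flat vs flat trajectories), on [100, 305] with 21
equally spaced time points:

* non-differential genes: X_i(t) = 0;
* differential genes: X_i(t) = sum_{l=1..3} xi_il phi_l(t) with
  xi_il ~ N(0, lambda_l), (lambda_1, lambda_2, lambda_3) = (4, 2, 1).

Two-group model (group comparison), on [100, 244] with 15 ("wild") and 22
("mutant") equally spaced time points:

* X_ij(t) = sum_{l=1,2} (xi_il + gamma_ijl) psi_l(t), with
  xi_il ~ N(0, lambda_xi_l), (4, 2), drawn once per gene and shared by the
  groups, and gamma_ijl ~ N(0, lambda_gamma_l), (5, 3), drawn independently
  per group for differential genes only (gamma = 0 otherwise).

Sharing the xi scores makes non-differential genes satisfy the null
hypothesis exactly -- identical underlying curves in both groups, differing
only by measurement noise -- while differential genes differ through their
group-specific gamma perturbations.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fpca import ExpressionMatrix

__all__ = [
    "SimulatedDataset",
    "basis_one_group",
    "basis_two_group",
    "simulate_one_group",
    "simulate_two_group",
    "ONE_GROUP_INTERVAL",
    "TWO_GROUP_INTERVAL",
    "ONE_GROUP_EIGENVALUES",
    "TWO_GROUP_XI_VARIANCES",
    "TWO_GROUP_GAMMA_VARIANCES",
    "NOISE_VARIANCE",
]

ONE_GROUP_INTERVAL = (100.0, 305.0)
TWO_GROUP_INTERVAL = (100.0, 244.0)
ONE_GROUP_EIGENVALUES = (4.0, 2.0, 1.0)
TWO_GROUP_XI_VARIANCES = (4.0, 2.0)
TWO_GROUP_GAMMA_VARIANCES = (5.0, 3.0)
NOISE_VARIANCE = 0.01


@dataclass
class SimulatedDataset:
    """Generated expression data plus ground truth.

    ``data`` is one ExpressionMatrix (one-group mode) or a list of two
    (two-group mode); ``truth`` flags the differential genes; ``params``
    records the generating parameters.
    """

    data: ExpressionMatrix | list[ExpressionMatrix]
    truth: np.ndarray
    params: dict

    @property
    def groups(self) -> list[ExpressionMatrix]:
        return self.data if isinstance(self.data, list) else [self.data]


def _fourier_basis(t: np.ndarray, a: float, b: float, n_components: int) -> np.ndarray:
    """Orthonormal (in L^2[a,b]) cosine/sine basis used by both models.

    Components alternate -sqrt(2/T) cos and +sqrt(2/T) sin at increasing
    integer frequencies over the interval of length T = b - a.
    """
    t = np.asarray(t, float)
    if np.any(t < a) or np.any(t > b):
        raise ValueError(f"times must lie within [{a}, {b}]")
    span = b - a
    amp = np.sqrt(2.0 / span)
    u = 2.0 * np.pi * (t - a) / span
    rows = []
    for l in range(n_components):
        freq = l // 2 + 1
        if l % 2 == 0:
            rows.append(-amp * np.cos(freq * u))
        else:
            rows.append(amp * np.sin(freq * u))
    return np.array(rows)


def basis_one_group(
    t: np.ndarray, a: float = ONE_GROUP_INTERVAL[0], b: float = ONE_GROUP_INTERVAL[1]
) -> np.ndarray:
    """The three basis functions of the one-group model, evaluated at t."""
    return _fourier_basis(t, a, b, 3)


def basis_two_group(
    t: np.ndarray, a: float = TWO_GROUP_INTERVAL[0], b: float = TWO_GROUP_INTERVAL[1]
) -> np.ndarray:
    """The two basis functions of the two-group model, evaluated at t."""
    return _fourier_basis(t, a, b, 2)


def _truth_labels(n: int, pi0: float, rng: np.random.Generator) -> np.ndarray:
    n_diff = int(round(pi0 * n))
    truth = np.zeros(n, dtype=bool)
    truth[rng.permutation(n)[:n_diff]] = True
    return truth


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


def simulate_one_group(
    n: int = 1000,
    pi0: float = 0.05,
    seed=None,
    times: np.ndarray | None = None,
) -> SimulatedDataset:
    """Generate a one-group dataset with a fraction ``pi0`` of non-flat genes."""
    if n < 2:
        raise ValueError("need at least 2 genes")
    if not 0 <= pi0 <= 1:
        raise ValueError("pi0 must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if times is None:
        times = np.linspace(*ONE_GROUP_INTERVAL, 21)
    times = np.asarray(times, float)
    phi = basis_one_group(times)
    truth = _truth_labels(n, pi0, rng)
    lam = np.asarray(ONE_GROUP_EIGENVALUES)
    xi = rng.normal(0.0, np.sqrt(lam), size=(int(truth.sum()), 3))
    x = np.zeros((n, len(times)))
    x[truth] = xi @ phi
    y = x + rng.normal(0.0, np.sqrt(NOISE_VARIANCE), size=x.shape)
    data = ExpressionMatrix(gene_ids=_gene_ids(n), times=times, values=y)
    params = {
        "mode": "one",
        "n": n,
        "pi0": pi0,
        "lambdas": tuple(lam),
        "sigma2": NOISE_VARIANCE,
        "times": times,
        "seed": seed,
    }
    return SimulatedDataset(data=data, truth=truth, params=params)


def simulate_two_group(
    n: int = 1000,
    pi0: float = 0.05,
    seed=None,
    times: tuple[np.ndarray, np.ndarray] | None = None,
) -> SimulatedDataset:
    """Generate a two-group dataset with a fraction ``pi0`` of differential genes."""
    if n < 2:
        raise ValueError("need at least 2 genes")
    if not 0 <= pi0 <= 1:
        raise ValueError("pi0 must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if times is None:
        times = (
            np.linspace(*TWO_GROUP_INTERVAL, 15),
            np.linspace(*TWO_GROUP_INTERVAL, 22),
        )
    truth = _truth_labels(n, pi0, rng)
    n_diff = int(truth.sum())
    lam_xi = np.asarray(TWO_GROUP_XI_VARIANCES)
    lam_gamma = np.asarray(TWO_GROUP_GAMMA_VARIANCES)
    ids = _gene_ids(n)
    xi = rng.normal(0.0, np.sqrt(lam_xi), size=(n, 2))  # shared across groups
    groups = []
    for tj in times:
        tj = np.asarray(tj, float)
        psi = basis_two_group(tj)
        coef = xi.copy()
        coef[truth] += rng.normal(0.0, np.sqrt(lam_gamma), size=(n_diff, 2))
        y = coef @ psi + rng.normal(0.0, np.sqrt(NOISE_VARIANCE), size=(n, len(tj)))
        groups.append(ExpressionMatrix(gene_ids=ids, times=tj, values=y))
    params = {
        "mode": "two",
        "n": n,
        "pi0": pi0,
        "lambda_xi": tuple(lam_xi),
        "lambda_gamma": tuple(lam_gamma),
        "sigma2": NOISE_VARIANCE,
        "times": tuple(np.asarray(t, float) for t in times),
        "seed": seed,
    }
    return SimulatedDataset(data=groups, truth=truth, params=params)
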