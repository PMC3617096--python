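"""Local polynomial kernel smoothers for covariance-surface estimation.

All smoothers use an (unnormalized) Gaussian kernel, solve a small weighted
least-squares problem at every target point, and are written for the dense
K x K covariance grids that arise when pooling genes: every pairwise
distance is formed explicitly, which is fine for K up to a few hundred.
"""
from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "local_linear_1d",
    "local_linear_surface",
    "local_quadratic_rotated",
    "gcv_bandwidth",
]


def _solve_wls(design: np.ndarray, weights: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Solve one weighted LS problem per target.

    design : (M, N, P) design matrices in target-relative coordinates
    weights: (M, N) kernel weights
    y      : (N,) responses
    Returns the (M, P) coefficient array.  A tiny ridge proportional to the
    trace keeps nearly-empty windows solvable; such windows are the caller's
    responsibility to avoid (see bandwidth enlargement in `fpca`).
    """
    xw = design * weights[:, :, None]
    a = np.einsum("mnp,mnq->mpq", xw, design)
    b = np.einsum("mnp,n->mp", xw, y)
    tr = np.trace(a, axis1=1, axis2=2)
    eye = np.eye(a.shape[-1])
    a = a + (1e-12 * tr[:, None, None] + 1e-300) * eye
    return np.linalg.solve(a, b[..., None])[..., 0]


def local_linear_1d(x: np.ndarray, y: np.ndarray, x0: np.ndarray, h: float) -> np.ndarray:
    """Local linear fit of y(x), evaluated at the points x0."""
    x = np.asarray(x, float)
    x0 = np.asarray(x0, float)
    dx = x0[:, None] - x[None, :]
    w = np.exp(-0.5 * (dx / h) ** 2)
    design = np.stack([np.ones_like(dx), dx], axis=-1)
    beta = _solve_wls(design, w, np.asarray(y, float))
    return beta[:, 0]


def local_linear_surface(
    coords: np.ndarray, z: np.ndarray, targets: np.ndarray, h: float
) -> np.ndarray:
    """2-D local linear fit of the surface z(s, t) at the given targets.

    coords  : (N, 2) data locations, z : (N,) values, targets : (M, 2).
    The same bandwidth h is used in both coordinates.
    """
    ds = targets[:, None, 0] - coords[None, :, 0]
    dt = targets[:, None, 1] - coords[None, :, 1]
    w = np.exp(-0.5 * ((ds / h) ** 2 + (dt / h) ** 2))
    design = np.stack([np.ones_like(ds), ds, dt], axis=-1)
    beta = _solve_wls(design, w, np.asarray(z, float))
    return beta[:, 0]


def local_quadratic_rotated(
    coords: np.ndarray, z: np.ndarray, t0: np.ndarray, h: float
) -> np.ndarray:
    """Diagonal values of a surface, extrapolated from off-diagonal data.

    The coordinates are rotated to u = (s + t)/2 (along the diagonal) and
    v = t - s (perpendicular to it); the fit is locally linear in u and
    quadratic in v, evaluated on the diagonal (v = 0) at u = t0.  Feeding
    only off-diagonal entries makes the returned values an estimate of the
    noise-free surface on the diagonal.
    """
    u = (coords[:, 0] + coords[:, 1]) / 2.0
    v = coords[:, 1] - coords[:, 0]
    t0 = np.asarray(t0, float)
    du = t0[:, None] - u[None, :]
    vv = np.broadcast_to(v[None, :], du.shape)
    w = np.exp(-0.5 * ((du / h) ** 2 + (vv / h) ** 2))
    design = np.stack([np.ones_like(du), du, vv**2], axis=-1)
    beta = _solve_wls(design, w, np.asarray(z, float))
    return beta[:, 0]


def _gcv_score(coords: np.ndarray, z: np.ndarray, h: float) -> float:
    """Generalized cross-validation score of the 2-D local linear smoother.

    The fit is evaluated at the data points themselves; the trace of the hat
    matrix follows from the self-weight of each point (a Gaussian kernel
    gives itself weight 1, and the target-relative design row is e1).
    """
    z = np.asarray(z, float)
    n = len(z)
    ds = coords[:, None, 0] - coords[None, :, 0]
    dt = coords[:, None, 1] - coords[None, :, 1]
    w = np.exp(-0.5 * ((ds / h) ** 2 + (dt / h) ** 2))
    design = np.stack([np.ones_like(ds), ds, dt], axis=-1)
    xw = design * w[:, :, None]
    a = np.einsum("mnp,mnq->mpq", xw, design)
    tr = np.trace(a, axis1=1, axis2=2)
    a = a + (1e-12 * tr[:, None, None] + 1e-300) * np.eye(3)
    b = np.einsum("mnp,n->mp", xw, z)
    try:
        beta = np.linalg.solve(a, b[..., None])[..., 0]
        ainv = np.linalg.inv(a)
    except np.linalg.LinAlgError:
        return np.inf
    fitted = beta[:, 0]
    trace_hat = float(ainv[:, 0, 0].sum())
    if trace_hat >= n:
        return np.inf
    rss = float(((z - fitted) ** 2).sum())
    return n * rss / (n - trace_hat) ** 2


def gcv_bandwidth(
    coords: np.ndarray, z: np.ndarray, candidates: np.ndarray
) -> tuple[float, np.ndarray]:
    """Pick the bandwidth minimizing the GCV score over the candidate grid."""
    scores = np.array([_gcv_score(coords, z, h) for h in candidates])
    if not np.isfinite(scores).any():
        raise ValueError("GCV failed for every candidate bandwidth")
    best = int(np.nanargmin(scores))
    h = float(candidates[best])
    logger.debug("GCV selected bandwidth %.4g (scores: %s)", h, scores)
    return h, scores
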