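"""Functional principal component analysis for pooled gene-expression curves.

Expression trajectories are modelled by a Karhunen-Loeve expansion
``X(t) = mu(t) + sum_l xi_l phi_l(t)`` whose eigenfunctions ``phi_l`` are
estimated from a covariance surface pooled across *all* genes of one
experimental group.  Because thousands of genes share the covariance, the
surface is estimated far more stably than any gene-specific smoother could
manage, which is what makes downstream testing powerful for short series
without replicates.

Pipeline (see :func:`fit_fpca`):

1. subtract each gene's own mean over time (magnitude differences between
   genes would otherwise dominate the covariance);
2. form the empirical covariance of the centered data on the K x K grid of
   sampling times;
3. smooth it with a 2-D local linear smoother, excluding the diagonal,
   whose entries carry the measurement-noise variance sigma^2 on top of the
   smooth surface;
4. estimate sigma^2 from the size of the diagonal ridge;
5. solve the quadrature-weighted eigenproblem for eigenvalues/eigenfunctions,
   keep enough components to pass a fraction-of-variation-explained rule;
6. estimate per-gene scores by trapezoid integration and reconstruct the
   fitted trajectories.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from ._smoothing import (
    gcv_bandwidth,
    local_linear_1d,
    local_linear_surface,
    local_quadratic_rotated,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "CenteredMatrix",
    "CovarianceEstimate",
    "EigenSystem",
    "FPCAFit",
    "FPCAResult",
    "center_by_gene_mean",
    "raw_covariance",
    "smooth_covariance",
    "estimate_noise_variance",
    "eigendecompose",
    "select_components",
    "estimate_scores",
    "reconstruct",
    "fit_fpca",
    "trapezoid_weights",
]


def trapezoid_weights(times: np.ndarray) -> np.ndarray:
    """Trapezoid quadrature weights for a (sorted) time grid.

    Repeated time values (which arise when permuted multi-group samples put
    two observations at the same time) contribute zero-length segments and
    are handled naturally.
    """
    t = np.asarray(times, float)
    if t.size < 2:
        raise ValueError("need at least two time points for quadrature")
    d = np.diff(t)
    w = np.empty_like(t)
    w[0] = d[0] / 2.0
    w[-1] = d[-1] / 2.0
    if t.size > 2:
        w[1:-1] = (d[:-1] + d[1:]) / 2.0
    return w


# ---------------------------------------------------------------------------
# containers


@dataclass
class ExpressionMatrix:
    """One experimental group's observations: genes x ordered sampling times.

    ``values[i, k]`` is the (log-scale) expression of gene i at time
    ``times[k]``; ``observed`` marks which entries are present.  Each gene
    needs at least three observed values for the mean/covariance machinery
    to be meaningful.
    """

    gene_ids: list[str]
    times: np.ndarray
    values: np.ndarray
    observed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.values = np.asarray(self.values, float)
        self.gene_ids = list(self.gene_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x times matrix")
        n, k = self.values.shape
        if len(self.gene_ids) != n:
            raise ValueError("gene_ids length does not match values")
        if self.times.shape != (k,):
            raise ValueError("times length does not match values")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(set(self.gene_ids)) != n:
            raise ValueError("duplicate gene_ids")
        if self.observed is None:
            self.observed = ~np.isnan(self.values)
        else:
            self.observed = np.asarray(self.observed, bool)
            if self.observed.shape != self.values.shape:
                raise ValueError("observed mask shape mismatch")
            self.observed = self.observed & ~np.isnan(self.values)
        counts = self.observed.sum(axis=1)
        if np.any(counts < 3):
            bad = self.gene_ids[int(np.argmin(counts))]
            raise ValueError(
                f"gene {bad!r} has fewer than 3 observed values"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]


@dataclass
class CenteredMatrix:
    """Gene-mean-centered expression values (zeros at missing entries)."""

    gene_means: np.ndarray
    centered: np.ndarray
    observed: np.ndarray
    times: np.ndarray
    gene_ids: list[str]


@dataclass
class CovarianceEstimate:
    """Raw and smoothed pooled covariance with the noise-variance estimate."""

    grid: np.ndarray
    raw: np.ndarray
    smooth: np.ndarray
    sigma2: float
    bandwidth: float


@dataclass
class EigenSystem:
    """Eigenvalues/eigenfunctions of the smoothed covariance surface.

    Eigenfunctions are orthonormal in L^2[a, b] under trapezoid quadrature
    on the grid.  ``L`` is the number of components retained for curve
    reconstruction (set by :func:`select_components`).
    """

    eigenvalues: np.ndarray
    eigenfunctions: np.ndarray  # (L_max, K)
    fve: np.ndarray
    grid: np.ndarray
    L: int = field(default=0)

    def __post_init__(self) -> None:
        if self.L == 0:
            self.L = len(self.eigenvalues)


@dataclass
class FPCAFit:
    """Per-gene scores, fitted trajectories and residual sums of squares."""

    scores: np.ndarray  # (n, L)
    fitted: np.ndarray  # (n, K), includes the gene mean
    rss: np.ndarray  # (n,), over observed entries


@dataclass
class FPCAResult:
    """Bundle returned by :func:`fit_fpca`."""

    centered: CenteredMatrix
    covariance: CovarianceEstimate
    eig: EigenSystem
    fit: FPCAFit


# ---------------------------------------------------------------------------
# operations


def center_by_gene_mean(data: ExpressionMatrix) -> CenteredMatrix:
    """Subtract each gene's mean (over its observed values) from its row.

    Centering per gene removes magnitude differences between genes so that
    the pooled covariance captures shape variation only.
    """
    obs = data.observed
    counts = obs.sum(axis=1)
    if np.any(counts < 3):
        bad = data.gene_ids[int(np.argmin(counts))]
        raise ValueError(f"gene {bad!r} has fewer than 3 observed values")
    vals = np.where(obs, data.values, 0.0)
    means = vals.sum(axis=1) / counts
    centered = np.where(obs, data.values - means[:, None], 0.0)
    return CenteredMatrix(
        gene_means=means,
        centered=centered,
        observed=obs.copy(),
        times=data.times.copy(),
        gene_ids=list(data.gene_ids),
    )


def raw_covariance(c: CenteredMatrix) -> np.ndarray:
    """Empirical covariance pooled over genes, with pairwise-complete counts.

    ``C[k, l]`` averages ``centered[i, k] * centered[i, l]`` over the genes
    observed at both k and l.  Pairs never co-observed come back as NaN and
    are skipped by the surface smoother.
    """
    if c.centered.shape[0] < 2:
        raise ValueError("need at least 2 genes for a pooled covariance")
    x = c.centered
    o = c.observed.astype(float)
    s = x.T @ x
    n_kl = o.T @ o
    with np.errstate(invalid="ignore"):
        cov = np.where(n_kl > 0, s / np.where(n_kl > 0, n_kl, 1.0), np.nan)
    return (cov + cov.T) / 2.0


def _default_bandwidth_grid(grid: np.ndarray) -> np.ndarray:
    dt_med = float(np.median(np.diff(grid)))
    span = float(grid[-1] - grid[0])
    return np.geomspace(0.5 * dt_med, span / 2.0, 10)


def _offdiag_entries(raw: np.ndarray, grid: np.ndarray):
    k = len(grid)
    s, t = np.meshgrid(grid, grid, indexing="ij")
    mask = ~np.eye(k, dtype=bool) & np.isfinite(raw)
    coords = np.column_stack([s[mask], t[mask]])
    return coords, raw[mask]


def smooth_covariance(
    raw: np.ndarray, grid: np.ndarray, bandwidth: float | str = "gcv"
) -> tuple[np.ndarray, float]:
    """Smooth the raw covariance on the full grid, excluding the diagonal.

    The diagonal entries of ``raw`` carry the noise variance on top of the
    surface, so they are dropped from the fit; the smoother then fills the
    diagonal back in from the off-diagonal neighbourhood.  With
    ``bandwidth="gcv"`` the bandwidth is chosen by generalized
    cross-validation over a 10-point logarithmic grid spanning half the
    median time spacing up to half the time range.
    """
    grid = np.asarray(grid, float)
    k = len(grid)
    if k < 4:
        raise ValueError("need at least 4 time points to smooth a surface")
    raw = np.asarray(raw, float)
    if not np.allclose(raw, raw.T, equal_nan=True, atol=1e-8):
        raise ValueError("raw covariance must be symmetric")
    coords, z = _offdiag_entries(raw, grid)
    if bandwidth == "gcv":
        h, _ = gcv_bandwidth(coords, z, _default_bandwidth_grid(grid))
    else:
        h = float(bandwidth)
        if h <= 0:
            raise ValueError("bandwidth must be positive")
    # enlarge until every target has effective data in its window
    s, t = np.meshgrid(grid, grid, indexing="ij")
    targets = np.column_stack([s.ravel(), t.ravel()])
    while True:
        d2 = ((targets[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
        wsum = np.exp(-0.5 * d2 / h**2).sum(axis=1)
        if wsum.min() > 1e-10:
            break
        h *= 1.5
        logger.warning(
            "bandwidth too small for some grid points; enlarged to %.4g", h
        )
    fitted = local_linear_surface(coords, z, targets, h).reshape(k, k)
    smooth = (fitted + fitted.T) / 2.0
    return smooth, h


def estimate_noise_variance(
    raw: np.ndarray,
    grid: np.ndarray,
    bandwidth: float | str = "gcv",
    trim: float = 0.10,
) -> float:
    """Estimate the measurement-noise variance sigma^2 from the diagonal ridge.

    The diagonal of the raw covariance equals the smooth surface plus
    sigma^2.  A 1-D local linear smoother along the diagonal (keeping the
    contaminated entries) is compared with a local quadratic smoother in the
    direction perpendicular to the diagonal (using off-diagonal entries
    only); their averaged difference over the central portion of the grid
    (trimming ``trim`` of the range at each end) estimates sigma^2, clipped
    below at zero.
    """
    grid = np.asarray(grid, float)
    if len(grid) < 5:
        raise ValueError("need at least 5 time points to estimate sigma^2")
    raw = np.asarray(raw, float)
    coords, z = _offdiag_entries(raw, grid)
    if bandwidth == "gcv":
        h, _ = gcv_bandwidth(coords, z, _default_bandwidth_grid(grid))
    else:
        h = float(bandwidth)
    diag = np.diag(raw)
    ok = np.isfinite(diag)
    diag_fit = local_linear_1d(grid[ok], diag[ok], grid, h)
    ridge_free = local_quadratic_rotated(coords, z, grid, h)
    span = grid[-1] - grid[0]
    central = (grid >= grid[0] + trim * span) & (grid <= grid[-1] - trim * span)
    sigma2 = float(np.mean(diag_fit[central] - ridge_free[central]))
    if sigma2 < 0:
        logger.warning("negative noise-variance estimate %.3g clipped to 0", sigma2)
        sigma2 = 0.0
    return sigma2


def eigendecompose(smooth: np.ndarray, grid: np.ndarray) -> EigenSystem:
    """Solve the quadrature-weighted eigenproblem of the smoothed surface.

    With W the diagonal matrix of trapezoid weights, the symmetric problem
    ``W^{1/2} G W^{1/2} u = lambda u`` is solved densely; eigenfunctions
    ``phi = W^{-1/2} u`` are then orthonormal in L^2[a, b] under trapezoid
    quadrature.  Non-positive eigenvalues (smoothed surfaces need not be
    PSD) are dropped.  Signs are fixed so each eigenfunction's entry of
    largest magnitude is positive.
    """
    grid = np.asarray(grid, float)
    smooth = np.asarray(smooth, float)
    if not np.allclose(smooth, smooth.T, atol=1e-8):
        raise ValueError("smoothed covariance must be symmetric")
    w = trapezoid_weights(grid)
    sq = np.sqrt(w)
    b = sq[:, None] * smooth * sq[None, :]
    b = (b + b.T) / 2.0
    vals, vecs = scipy.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    keep = vals > 0
    if not keep.any():
        raise ValueError("covariance estimate has no positive component")
    vals = vals[keep]
    phi = (vecs[:, keep] / sq[:, None]).T  # (L_max, K)
    flip = phi[np.arange(len(vals)), np.argmax(np.abs(phi), axis=1)] < 0
    phi[flip] *= -1.0
    fve = np.cumsum(vals) / vals.sum()
    return EigenSystem(
        eigenvalues=vals, eigenfunctions=phi, fve=fve, grid=grid.copy()
    )


def select_components(
    eigenvalues: np.ndarray, method: str = "fve", threshold: float = 0.90
) -> int:
    """Smallest number of components whose cumulative FVE exceeds threshold."""
    if method != "fve":
        raise ValueError(f"unknown selection method {method!r}")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    vals = np.asarray(eigenvalues, float)
    vals = vals[vals > 0]
    if vals.size == 0:
        raise ValueError("need at least one positive eigenvalue")
    fve = np.cumsum(vals) / vals.sum()
    above = np.nonzero(fve > threshold)[0]
    return int(above[0]) + 1 if above.size else len(vals)


def _fill_missing(values: np.ndarray, observed: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Linear interpolation inside the range, nearest-value extension outside."""
    if observed.all():
        return values
    filled = values.copy()
    for i in np.nonzero(~observed.all(axis=1))[0]:
        obs = observed[i]
        filled[i] = np.interp(times, times[obs], values[i, obs])
    return filled


def estimate_scores(
    c: CenteredMatrix, eig: EigenSystem, L: int | None = None
) -> np.ndarray:
    """Integral score estimates xi_il = int centered_i(t) phi_l(t) dt.

    Dense-design estimator: the integral is approximated by the trapezoid
    rule on the grid.  Missing entries are filled by linear interpolation
    first (nearest value at the ends).
    """
    if L is None:
        L = eig.L
    filled = _fill_missing(c.centered, c.observed, c.times)
    w = trapezoid_weights(c.times)
    a = (eig.eigenfunctions[:L] * w).T  # (K, L)
    return filled @ a


def reconstruct(
    data: ExpressionMatrix,
    centered: CenteredMatrix,
    scores: np.ndarray,
    eig: EigenSystem,
) -> FPCAFit:
    """Fitted trajectories mu_i + sum_l xi_il phi_l(t) and their RSS.

    The residual sum of squares is taken over observed entries only.
    """
    L = scores.shape[1]
    fitted = centered.gene_means[:, None] + scores @ eig.eigenfunctions[:L]
    resid = np.where(data.observed, np.nan_to_num(data.values) - fitted, 0.0)
    rss = (resid**2).sum(axis=1)
    return FPCAFit(scores=scores, fitted=fitted, rss=rss)


def fit_fpca(
    data: ExpressionMatrix,
    fve_threshold: float = 0.90,
    bandwidth: float | str = "gcv",
) -> FPCAResult:
    """Run the full FPCA pipeline on one group's expression matrix."""
    centered = center_by_gene_mean(data)
    raw = raw_covariance(centered)
    smooth, h = smooth_covariance(raw, data.times, bandwidth)
    sigma2 = estimate_noise_variance(raw, data.times, h)
    eig = eigendecompose(smooth, data.times)
    eig.L = select_components(eig.eigenvalues, threshold=fve_threshold)
    logger.debug(
        "FPCA: bandwidth=%.4g sigma2=%.4g L=%d (FVE %.3f)",
        h,
        sigma2,
        eig.L,
        eig.fve[eig.L - 1],
    )
    scores = estimate_scores(centered, eig)
    fit = reconstruct(data, centered, scores, eig)
    cov = CovarianceEstimate(
        grid=data.times.copy(), raw=raw, smooth=smooth, sigma2=sigma2, bandwidth=h
    )
    return FPCAResult(centered=centered, covariance=cov, eig=eig, fit=fit)
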