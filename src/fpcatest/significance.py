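"""Permutation F-tests for time-course differential expression.

One-group test: is a gene's trajectory flat?  The null fit is the gene's
own mean; the alternative fit is the FPCA reconstruction.  The test
statistic is a variance-stabilized F ratio on the mean-squared-residual
scale,

    F_i = (RSS_i0/K_i - RSS_i1/K_i) / (RSS_i1/K_i + delta),

with K_i the gene's number of observed values and delta = sigma2_hat the
estimated per-observation noise variance.  Normalizing by K_i puts the
residual term on the same (per-observation variance) scale as the
stabilizer: genes with large overall variance then face a genuinely larger
denominator floor, which is what tames the pooled null's false positives,
and genes with missing values are handled by their own K_i.  The null
distribution is generated by randomly re-matching each gene's expression
measurements with its sampling times.  For efficiency the eigenfunctions
(and delta) estimated from the observed data are reused for every
permutation sample.

Multi-group test: do the groups share one trajectory?  The alternative
fits each group separately (its own eigensystem); the null fits the pooled
observations of all groups; delta is the largest per-group noise-variance
estimate.  The permutation re-partitions the pooled observations at each
time point -- or within small time bins when the groups' sampling grids
differ -- into groups of the original sizes.

p-values come in two flavours: "genewise" counts only a gene's own
permutation statistics; "pooled" counts exceedances over the statistics of
all genes, which preserves the ordering of the F statistics and gives
fewer false positives.  Multiplicity is handled by Benjamini-Hochberg
step-up FDR control.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .fpca import (
    CenteredMatrix,
    EigenSystem,
    ExpressionMatrix,
    FPCAResult,
    _fill_missing,
    center_by_gene_mean,
    eigendecompose,
    estimate_scores,
    fit_fpca,
    raw_covariance,
    select_components,
    smooth_covariance,
    estimate_noise_variance,
    trapezoid_weights,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FTestResult",
    "PermutationNull",
    "BinScheme",
    "f_statistic",
    "bh_adjust",
    "pvalues_genewise",
    "pvalues_pooled",
    "fit_one_group",
    "permute_one_group",
    "one_group_test",
    "make_bins",
    "fit_multi_group",
    "permute_multi_group",
    "multi_group_test",
]

DELTA_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# containers


@dataclass
class FTestResult:
    """Per-gene test output plus the run's settings in ``info``."""

    gene_ids: list[str]
    rss0: np.ndarray
    rss1: np.ndarray
    delta: float
    f: np.ndarray
    p: np.ndarray
    p_adjusted: np.ndarray
    rejected: np.ndarray
    info: dict = field(default_factory=dict)


@dataclass
class PermutationNull:
    """B x n matrix of F statistics from permutation samples."""

    stats: np.ndarray
    B: int
    seed: object = None


@dataclass
class BinScheme:
    """Partition of the time interval used for multi-group permutation.

    ``assignment[j][k]`` is the bin index of group j's k-th time point, or
    -1 when the containing bin was dropped (some group had no observation
    there); dropped observations keep their original group labels but still
    enter the F statistics.
    """

    edges: np.ndarray
    assignment: list[np.ndarray]
    dropped_bins: list[int]


# ---------------------------------------------------------------------------
# statistic, p-values, FDR


def f_statistic(rss0, rss1, delta):
    """Variance-stabilized goodness-of-fit ratio (RSS0 - RSS1)/(RSS1 + delta)."""
    rss0 = np.asarray(rss0, float)
    rss1 = np.asarray(rss1, float)
    if np.any(rss0 < 0) or np.any(rss1 < 0):
        raise ValueError("residual sums of squares must be nonnegative")
    if delta <= 0:
        raise ValueError("delta must be positive")
    return (rss0 - rss1) / (rss1 + delta)


def pvalues_genewise(observed_f, null: PermutationNull, smoothed: bool = False):
    """p_i = #{b : F_i^(b) >= F_i} / B, counting each gene's own null only.

    ``smoothed=True`` applies the +1/(B+1) correction that keeps p-values
    away from zero; the plain count is the default.
    """
    f = np.asarray(observed_f, float)
    cnt = (null.stats >= f[None, :]).sum(axis=0)
    if smoothed:
        return (cnt + 1) / (null.B + 1)
    return cnt / null.B


def pvalues_pooled(observed_f, null: PermutationNull, smoothed: bool = False):
    """p_i counting exceedances over the null statistics of all genes.

    p_i = #{(b, j) : F_j^(b) >= F_i} / (n B); ties in the observed F get
    equal p-values, and larger F can never get a larger p-value.
    """
    f = np.asarray(observed_f, float)
    flat = np.sort(null.stats.ravel())
    total = flat.size
    cnt = total - np.searchsorted(flat, f, side="left")
    if smoothed:
        return (cnt + 1) / (total + 1)
    return cnt / total


def bh_adjust(p, level: float = 0.05):
    """Benjamini-Hochberg step-up adjustment; returns (p_adjusted, rejected)."""
    p = np.asarray(p, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy(), np.zeros(0, bool)
    rejected, p_adj, _, _ = multipletests(p, alpha=level, method="fdr_bh")
    return p_adj, rejected


# ---------------------------------------------------------------------------
# one-group test


def _stabilized_f(rss0, rss1, n_obs, delta):
    """F on the mean-squared-residual scale; n_obs = observations per gene."""
    return f_statistic(rss0 / n_obs, rss1 / n_obs, delta)


@dataclass
class OneGroupFit:
    """Observed-data fit of the one-group test (inputs to the permutation)."""

    fpca: FPCAResult
    rss0: np.ndarray
    rss1: np.ndarray
    n_obs: np.ndarray
    delta: float
    f: np.ndarray


def fit_one_group(
    data: ExpressionMatrix,
    fve_threshold: float = 0.90,
    bandwidth: float | str = "gcv",
) -> OneGroupFit:
    """Fit null (gene mean) and alternative (FPCA) models and form F."""
    res = fit_fpca(data, fve_threshold=fve_threshold, bandwidth=bandwidth)
    rss0 = (res.centered.centered**2).sum(axis=1)
    rss1 = res.fit.rss
    n_obs = data.observed.sum(axis=1)
    delta = max(res.covariance.sigma2, DELTA_FLOOR)
    f = _stabilized_f(rss0, rss1, n_obs, delta)
    return OneGroupFit(fpca=res, rss0=rss0, rss1=rss1, n_obs=n_obs,
                       delta=delta, f=f)


def permute_one_group(
    centered: CenteredMatrix,
    eig: EigenSystem,
    delta: float,
    B: int,
    seed=None,
    permutations: np.ndarray | None = None,
    per_gene: bool = True,
    chunk: int = 200,
) -> PermutationNull:
    """Null F statistics from random re-matchings of values and times.

    By default each gene's measurements are independently re-matched with
    the sampling times; ``per_gene=False`` instead applies one permutation
    of the K time labels identically to every gene, preserving inter-gene
    correlation under the null.  Eigenfunctions and delta stay frozen at
    their observed-data values; gene means and per-gene observation counts
    are permutation-invariant, so RSS0 is reused.  ``permutations`` (a
    (B, K) array of index permutations, applied to all genes) overrides the
    random draw; handy for identity or exhaustive checks.
    """
    rng = np.random.default_rng(seed)
    C = centered.centered
    obs = centered.observed
    n, K = C.shape
    L = eig.L
    phi = eig.eigenfunctions[:L]
    w = trapezoid_weights(centered.times)
    A = (phi * w).T  # (K, L)
    rss0 = (C**2).sum(axis=1)
    n_obs = obs.sum(axis=1)
    fully_observed = bool(obs.all())

    if permutations is not None:
        perms = np.asarray(permutations, int)
        B = perms.shape[0]
        per_gene = False
    elif not per_gene:
        perms = np.argsort(rng.random((B, K)), axis=1)
    else:
        perms = None

    stats = np.empty((B, n))
    if per_gene:
        for b in range(B):
            pm = np.argsort(rng.random((n, K)), axis=1)
            cp = np.take_along_axis(C, pm, axis=1)
            op = np.take_along_axis(obs, pm, axis=1)
            stats[b] = _refit_f(cp, op, centered.times, A, phi, rss0, n_obs,
                                delta, fully_observed)
        return PermutationNull(stats=stats, B=B, seed=seed)

    if fully_observed:
        inv = np.argsort(perms, axis=1)
        pt = phi.T  # (K, L)
        gram = phi @ phi.T  # (L, L), plain grid-point sums
        for start in range(0, B, chunk):
            sl = slice(start, min(start + chunk, B))
            a_b = A[inv[sl]]  # (cB, K, L)
            p_b = pt[inv[sl]]
            xi = np.einsum("nk,bkl->nbl", C, a_b)
            eta = np.einsum("nk,bkl->nbl", C, p_b)
            quad = np.einsum("nbl,lm,nbm->nb", xi, gram, xi)
            rss1 = rss0[:, None] - 2.0 * (xi * eta).sum(axis=-1) + quad
            mss1 = rss1 / n_obs[:, None]
            f = (rss0[:, None] / n_obs[:, None] - mss1) / (mss1 + delta)
            stats[sl] = f.T
    else:
        for b in range(B):
            pm = perms[b]
            stats[b] = _refit_f(C[:, pm], obs[:, pm], centered.times, A, phi,
                                rss0, n_obs, delta, False)
    return PermutationNull(stats=stats, B=B, seed=seed)


def _refit_f(cp, op, times, A, phi, rss0, n_obs, delta, fully_observed):
    """Recompute F for one permuted layout (general, mask-aware path)."""
    filled = cp if fully_observed else _fill_missing(cp, op, times)
    xi = filled @ A
    dev = xi @ phi
    resid = np.where(op, cp - dev, 0.0)
    rss1 = (resid**2).sum(axis=1)
    return (rss0 / n_obs - rss1 / n_obs) / (rss1 / n_obs + delta)


def one_group_test(
    data: ExpressionMatrix,
    fve_threshold: float = 0.90,
    B: int = 10000,
    seed=None,
    pvalue_mode: str = "pooled",
    fdr_level: float = 0.05,
    bandwidth: float | str = "gcv",
    per_gene_permutation: bool = True,
    smoothed_pvalues: bool = False,
) -> FTestResult:
    """Test every gene for a non-flat expression trajectory."""
    if B < 100:
        logger.warning("B=%d permutations is small; p-values will be coarse", B)
    fit = fit_one_group(data, fve_threshold=fve_threshold, bandwidth=bandwidth)
    null = permute_one_group(
        fit.fpca.centered, fit.fpca.eig, fit.delta, B, seed=seed,
        per_gene=per_gene_permutation,
    )
    if pvalue_mode == "pooled":
        p = pvalues_pooled(fit.f, null, smoothed=smoothed_pvalues)
    elif pvalue_mode == "genewise":
        p = pvalues_genewise(fit.f, null, smoothed=smoothed_pvalues)
    else:
        raise ValueError(f"unknown pvalue_mode {pvalue_mode!r}")
    p_adj, rejected = bh_adjust(p, fdr_level)
    info = {
        "test": "one-group",
        "delta": fit.delta,
        "sigma2": fit.fpca.covariance.sigma2,
        "L": fit.fpca.eig.L,
        "bandwidth": fit.fpca.covariance.bandwidth,
        "B": B,
        "seed": seed,
        "pvalue_mode": pvalue_mode,
        "fdr_level": fdr_level,
        "permutation": "per-gene" if per_gene_permutation else "joint",
    }
    return FTestResult(
        gene_ids=list(data.gene_ids), rss0=fit.rss0, rss1=fit.rss1,
        delta=fit.delta, f=fit.f, p=p, p_adjusted=p_adj, rejected=rejected,
        info=info,
    )


# ---------------------------------------------------------------------------
# multi-group test


def make_bins(groups: list[ExpressionMatrix], bin_width: float) -> BinScheme:
    """Partition [a, b] into contiguous bins of the given width.

    Bins in which any group has no observation are dropped from the
    permutation (their observations still enter the F statistics); bins
    with no observations at all are dropped silently.  The last bin is
    closed so the right endpoint belongs to it.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    times_list = [np.asarray(g.times, float) for g in groups]
    a = min(t[0] for t in times_list)
    b = max(t[-1] for t in times_list)
    m = max(1, int(np.ceil((b - a) / bin_width - 1e-9)))
    edges = a + bin_width * np.arange(m + 1)
    assignment = []
    counts = np.zeros((m, len(groups)), int)
    for j, t in enumerate(times_list):
        idx = np.minimum((np.floor((t - a) / bin_width + 1e-12)).astype(int), m - 1)
        assignment.append(idx)
        np.add.at(counts, (idx, j), 1)
    occupied = counts.sum(axis=1) > 0
    complete = (counts > 0).all(axis=1)
    dropped = np.nonzero(~complete)[0]
    for d in dropped:
        if occupied[d]:
            missing = np.nonzero(counts[d] == 0)[0]
            logger.warning(
                "bin [%.4g, %.4g) has no observations from group(s) %s; "
                "dropped from permutation",
                edges[d], edges[d + 1], ", ".join(str(j + 1) for j in missing),
            )
    if not complete.any():
        raise ValueError("every bin lacks observations from some group")
    for j in range(len(groups)):
        assignment[j] = np.where(complete[assignment[j]], assignment[j], -1)
    return BinScheme(edges=edges, assignment=assignment,
                     dropped_bins=[int(d) for d in dropped])


def _per_timepoint_scheme(groups: list[ExpressionMatrix]) -> BinScheme:
    """Each shared time point is its own bin; grids must coincide."""
    t0 = groups[0].times
    for g in groups[1:]:
        if len(g.times) != len(t0) or not np.allclose(g.times, t0):
            raise ValueError(
                "per-time-point permutation needs identical sampling grids "
                "across groups; supply bin_width for differing grids"
            )
    idx = np.arange(len(t0))
    edges = np.append(t0, t0[-1])
    return BinScheme(edges=edges, assignment=[idx.copy() for _ in groups],
                     dropped_bins=[])


@dataclass
class MultiGroupFit:
    """Observed-data fits of the multi-group test, flattened to columns.

    Observations of all groups are laid out as columns of one n x M matrix
    so permutations become shuffles of the per-column group labels.  The
    frozen eigensystems are pre-evaluated at every column's time so a
    permuted group can be re-fit at whatever times it ends up holding.
    """

    groups: list[ExpressionMatrix]
    gene_ids: list[str]
    col_values: np.ndarray  # (n, M), missing entries interpolated
    col_times: np.ndarray  # (M,)
    col_group: np.ndarray  # (M,)
    group_eigs: list[EigenSystem]
    group_phi_cols: list[np.ndarray]  # per group: (L_j, M)
    sigma2s: list[float]
    pooled_eig: EigenSystem
    rss0: np.ndarray
    rss1: np.ndarray
    n_obs: np.ndarray
    delta: float
    f: np.ndarray
    info: dict


def fit_multi_group(
    groups: list[ExpressionMatrix],
    fve_threshold: float = 0.90,
    bandwidth: float | str = "gcv",
) -> MultiGroupFit:
    """Fit per-group (alternative) and pooled (null) FPCA models.

    The alternative fits each group with its own eigensystem, component
    number and noise variance.  The null pools all observations: the
    per-gene mean is taken over every observation of every group, the
    covariance is estimated on the union time grid (observations sharing a
    time are averaged), and the fitted common curve is evaluated back at
    each group's times.  RSS are summed over groups; delta = max_j
    sigma2_j.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    ids = groups[0].gene_ids
    for g in groups[1:]:
        if g.gene_ids != ids:
            raise ValueError("gene_id lists differ across groups")
    n = groups[0].n_genes

    # alternative: separate FPCA per group
    rss1 = np.zeros(n)
    sigma2s, group_eigs, group_bandwidths = [], [], []
    for g in groups:
        res = fit_fpca(g, fve_threshold=fve_threshold, bandwidth=bandwidth)
        rss1 += res.fit.rss
        sigma2s.append(res.covariance.sigma2)
        group_eigs.append(res.eig)
        group_bandwidths.append(res.covariance.bandwidth)

    # column layout of the pooled observations
    col_times = np.concatenate([g.times for g in groups])
    col_group = np.concatenate(
        [np.full(g.n_times, j) for j, g in enumerate(groups)]
    )
    col_raw = np.concatenate([g.values for g in groups], axis=1)
    col_obs = np.concatenate([g.observed for g in groups], axis=1)
    if not col_obs.all():
        logger.info(
            "missing entries interpolated within groups before permutation"
        )
    col_values = np.concatenate(
        [_fill_missing(np.nan_to_num(g.values) * g.observed, g.observed, g.times)
         if not g.observed.all() else g.values for g in groups],
        axis=1,
    )

    # null: pooled mean over all observations, covariance on the union grid
    counts = col_obs.sum(axis=1)
    pooled_mean = np.where(col_obs, np.nan_to_num(col_raw), 0.0).sum(axis=1) / counts
    utimes, uinv = np.unique(np.round(col_times, 9), return_inverse=True)
    u = len(utimes)
    sums = np.zeros((n, u))
    cnts = np.zeros((n, u))
    np.add.at(sums.T, uinv, np.where(col_obs, np.nan_to_num(col_raw), 0.0).T)
    np.add.at(cnts.T, uinv, col_obs.T.astype(float))
    uobs = cnts > 0
    avg = np.where(uobs, sums / np.where(uobs, cnts, 1.0), 0.0)
    pooled_centered = CenteredMatrix(
        gene_means=pooled_mean,
        centered=np.where(uobs, avg - pooled_mean[:, None], 0.0),
        observed=uobs,
        times=utimes,
        gene_ids=list(ids),
    )
    raw0 = raw_covariance(pooled_centered)
    smooth0, h0 = smooth_covariance(raw0, utimes, bandwidth)
    pooled_eig = eigendecompose(smooth0, utimes)
    pooled_eig.L = select_components(pooled_eig.eigenvalues,
                                     threshold=fve_threshold)
    scores0 = estimate_scores(pooled_centered, pooled_eig)
    dev0 = scores0 @ pooled_eig.eigenfunctions[: pooled_eig.L]  # (n, U)
    # union grid contains every column time, so evaluation is a lookup
    fitted0_cols = pooled_mean[:, None] + dev0[:, uinv]
    resid0 = np.where(col_obs, np.nan_to_num(col_raw) - fitted0_cols, 0.0)
    rss0 = (resid0**2).sum(axis=1)

    delta = max(max(sigma2s), DELTA_FLOOR)
    n_obs = counts  # total observations per gene across groups
    f = _stabilized_f(rss0, rss1, n_obs, delta)

    # frozen group eigenfunctions evaluated at every column's time
    group_phi_cols = []
    for eig in group_eigs:
        phi = eig.eigenfunctions[: eig.L]
        group_phi_cols.append(
            np.array([np.interp(col_times, eig.grid, row) for row in phi])
        )

    info = {
        "test": "multi-group",
        "delta": delta,
        "sigma2_per_group": list(sigma2s),
        "L_per_group": [e.L for e in group_eigs],
        "L_pooled": pooled_eig.L,
        "bandwidth_per_group": group_bandwidths,
        "bandwidth_pooled": h0,
    }
    fit = MultiGroupFit(
        groups=groups, gene_ids=list(ids), col_values=col_values,
        col_times=col_times, col_group=col_group, group_eigs=group_eigs,
        group_phi_cols=group_phi_cols, sigma2s=sigma2s, pooled_eig=pooled_eig,
        rss0=rss0, rss1=rss1, n_obs=n_obs, delta=delta, f=f, info=info,
    )
    # the F entering permutation comparisons is produced by the same code
    # path as the null statistics, so exact ties (e.g. duplicated groups)
    # resolve consistently; it equals `f` up to float rounding when data are
    # fully observed
    ident = permute_multi_group(fit, None, B=1,
                                permutations=col_group[None, :])
    fit.f = ident.stats[0]
    return fit


def _column_bins(fit: MultiGroupFit, scheme: BinScheme) -> np.ndarray:
    """Bin index per column (-1 = not permuted), from the scheme's assignment."""
    col_bin = np.empty(len(fit.col_times), int)
    start = 0
    for j, g in enumerate(fit.groups):
        col_bin[start : start + g.n_times] = scheme.assignment[j]
        start += g.n_times
    return col_bin


def permute_multi_group(
    fit: MultiGroupFit,
    scheme: BinScheme,
    B: int,
    seed=None,
    permutations: np.ndarray | None = None,
    per_gene: bool = True,
    chunk: int = 64,
) -> PermutationNull:
    """Null F statistics from re-partitioning observations within bins.

    Within each retained bin the columns' group labels are shuffled, so
    the per-group observation counts per bin -- and hence the group sizes
    -- are preserved.  By default each gene's observations are
    re-partitioned independently; ``per_gene=False`` applies the same
    re-partition to every gene.  Eigensystems (per group and pooled) and
    delta stay frozen; the pooled observations are label-free, so RSS0 is
    permutation-invariant and only the per-group fits are recomputed,
    using each group's eigenfunctions evaluated at whatever times the
    permuted group holds.  ``permutations`` (a (B, M) array of group
    labels, applied to all genes) overrides the random draw for
    identity/exhaustive checks.
    """
    rng = np.random.default_rng(seed)
    values = fit.col_values
    tcol = fit.col_times
    gcol = fit.col_group
    n, m = values.shape
    n_groups = len(fit.groups)
    if permutations is None:
        col_bin = _column_bins(fit, scheme)
        bins = [np.nonzero(col_bin == bb)[0]
                for bb in np.unique(col_bin[col_bin >= 0])]
    else:
        col_bin = None
        bins = []
    tsort = np.argsort(tcol, kind="stable")
    rss0 = fit.rss0
    n_obs = fit.n_obs
    delta = fit.delta
    sizes = [g.n_times for g in fit.groups]

    if permutations is not None:
        permutations = np.asarray(permutations, int)
        B = permutations.shape[0]
        per_gene = False

    stats = np.empty((B, n))

    if per_gene and permutations is None:
        # one independent re-partition per gene per sample; batch over genes
        phi_cols = [p[:, tsort] for p in fit.group_phi_cols]
        vals_s = values[:, tsort]
        t_s = tcol[tsort]
        gcol_s = gcol[tsort]
        bins_s = [np.nonzero(col_bin[tsort] == bb)[0]
                  for bb in np.unique(col_bin[col_bin >= 0])]
        for b in range(B):
            labels = np.broadcast_to(gcol_s, (n, m)).copy()
            for idx in bins_s:
                order = np.argsort(rng.random((n, len(idx))), axis=1)
                labels[:, idx] = gcol_s[idx][order]
            rss1 = np.zeros(n)
            for j in range(n_groups):
                kj = sizes[j]
                rows, pos = np.nonzero(labels == j)
                idx = pos.reshape(n, kj)  # time-ordered (labels sorted by time)
                tj = t_s[idx]
                d = np.diff(tj, axis=1)
                w = np.empty_like(tj)
                w[:, 0] = d[:, 0] / 2.0
                w[:, -1] = d[:, -1] / 2.0
                if kj > 2:
                    w[:, 1:-1] = (d[:, :-1] + d[:, 1:]) / 2.0
                phi = phi_cols[j][:, idx]  # (L, n, kj)
                v = np.take_along_axis(vals_s, idx, axis=1)  # (n, kj)
                cc = v - v.mean(axis=1, keepdims=True)
                xi = np.einsum("nk,lnk->nl", cc * w, phi)
                dev = np.einsum("nl,lnk->nk", xi, phi)
                rss1 += ((cc - dev) ** 2).sum(axis=1)
            mss1 = rss1 / n_obs
            stats[b] = (rss0 / n_obs - mss1) / (mss1 + delta)
        return PermutationNull(stats=stats, B=B, seed=seed)

    for start in range(0, B, chunk):
        stop = min(start + chunk, B)
        cb = stop - start
        if permutations is not None:
            labels = permutations[start:stop]
        else:
            labels = np.broadcast_to(gcol, (cb, m)).copy()
            for idx in bins:
                order = np.argsort(rng.random((cb, len(idx))), axis=1)
                labels[:, idx] = gcol[idx][order]
        rss1 = np.zeros((n, cb))
        for j in range(n_groups):
            kj = sizes[j]
            mask = labels[:, tsort] == j  # (cb, M)
            rows, pos = np.nonzero(mask)
            idx = tsort[pos].reshape(cb, kj)  # time-ordered columns of group j
            tj = tcol[idx]  # (cb, kj)
            d = np.diff(tj, axis=1)
            w = np.empty_like(tj)
            w[:, 0] = d[:, 0] / 2.0
            w[:, -1] = d[:, -1] / 2.0
            if kj > 2:
                w[:, 1:-1] = (d[:, :-1] + d[:, 1:]) / 2.0
            phi = fit.group_phi_cols[j][:, idx].transpose(1, 0, 2)  # (cb, L, kj)
            v = values[:, idx]  # (n, cb, kj)
            mu = v.mean(axis=2)
            cc = v - mu[:, :, None]
            a = phi * w[:, None, :]
            xi = np.einsum("nbk,blk->nbl", cc, a)
            dev = np.einsum("nbl,blk->nbk", xi, phi)
            rss1 += ((cc - dev) ** 2).sum(axis=-1)
        mss1 = rss1 / n_obs[:, None]
        f = (rss0[:, None] / n_obs[:, None] - mss1) / (mss1 + delta)
        stats[start:stop] = f.T
    return PermutationNull(stats=stats, B=B, seed=seed)


def multi_group_test(
    groups: list[ExpressionMatrix],
    fve_threshold: float = 0.90,
    B: int = 10000,
    seed=None,
    pvalue_mode: str = "pooled",
    fdr_level: float = 0.05,
    bin_width: float | None = None,
    bandwidth: float | str = "gcv",
    smoothed_pvalues: bool = False,
) -> FTestResult:
    """Test every gene for differing trajectories across groups.

    With ``bin_width=None`` the permutation shuffles group labels at each
    shared time point (grids must coincide); otherwise labels are shuffled
    within time bins of the given width, which accommodates groups sampled
    on different grids.
    """
    if B < 100:
        logger.warning("B=%d permutations is small; p-values will be coarse", B)
    fit = fit_multi_group(groups, fve_threshold=fve_threshold,
                          bandwidth=bandwidth)
    if bin_width is None:
        scheme = _per_timepoint_scheme(groups)
    else:
        scheme = make_bins(groups, bin_width)
    null = permute_multi_group(fit, scheme, B, seed=seed)
    if pvalue_mode == "pooled":
        p = pvalues_pooled(fit.f, null, smoothed=smoothed_pvalues)
    elif pvalue_mode == "genewise":
        p = pvalues_genewise(fit.f, null, smoothed=smoothed_pvalues)
    else:
        raise ValueError(f"unknown pvalue_mode {pvalue_mode!r}")
    p_adj, rejected = bh_adjust(p, fdr_level)
    info = dict(fit.info)
    info.update({
        "B": B, "seed": seed, "pvalue_mode": pvalue_mode,
        "fdr_level": fdr_level,
        "bin_width": bin_width, "dropped_bins": scheme.dropped_bins,
    })
    return FTestResult(
        gene_ids=fit.gene_ids, rss0=fit.rss0, rss1=fit.rss1, delta=fit.delta,
        f=fit.f, p=p, p_adjusted=p_adj, rejected=rejected, info=info,
    )
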