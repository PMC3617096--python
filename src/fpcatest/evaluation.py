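"""Replicated simulation studies: false-positive rate and sensitivity.

`run_study` repeats simulate -> test -> score for a given setting and
averages the two operating characteristics used throughout:

* FPR: falsely rejected hypotheses over total rejections (the realized
  false discovery proportion; 0 when nothing is rejected);
* sensitivity: the fraction of truly differential genes rejected.

Both p-value definitions (pooled and genewise) are evaluated against the
same permutation null of each replicate, so their comparison is paired.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import significance as sig
from .simulate import simulate_one_group, simulate_two_group

logger = logging.getLogger(__name__)

__all__ = ["StudyResult", "fpr_sensitivity", "run_study", "study_table"]


@dataclass
class StudyResult:
    """Averaged operating characteristics for one (setting, FDR, p-mode) cell."""

    mode: str
    pi0: float
    fdr_level: float
    pvalue_mode: str
    reps: int
    fpr_mean: float
    sensitivity_mean: float
    per_rep: list[tuple[float, float]]
    B: int
    n: int
    seed: object


def fpr_sensitivity(rejected, truth) -> tuple[float, float]:
    """Score one replicate's rejections against the ground truth.

    Returns (fpr, sensitivity); fpr is 0 when nothing was rejected, and
    sensitivity is NaN when there are no truly differential genes.
    """
    rejected = np.asarray(rejected, bool)
    truth = np.asarray(truth, bool)
    if rejected.shape != truth.shape:
        raise ValueError("rejected and truth must have equal length")
    n_rej = int(rejected.sum())
    n_true = int(truth.sum())
    fp = int((rejected & ~truth).sum())
    tp = int((rejected & truth).sum())
    fpr = fp / n_rej if n_rej > 0 else 0.0
    sens = tp / n_true if n_true > 0 else float("nan")
    return fpr, sens


def run_study(
    mode: str,
    pi0: float,
    fdr_levels=(0.01, 0.05),
    pvalue_modes=("pooled", "genewise"),
    reps: int = 50,
    n: int = 1000,
    B: int = 1000,
    seed=None,
    fve_threshold: float = 0.90,
    bin_width: float | None = 10.0,
    bandwidth: float | str = "gcv",
) -> list[StudyResult]:
    """Replicate the simulation study for one setting.

    Each replicate draws a fresh dataset, runs the fit and the permutation
    null once, and then scores every (FDR level, p-value mode) combination
    against the ground truth.  A master seed spawns independent per-rep
    streams, so results are reproducible and the first replicates are
    unchanged when ``reps`` grows.
    """
    if mode not in ("one", "two"):
        raise ValueError("mode must be 'one' or 'two'")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    master = np.random.SeedSequence(seed)
    cells = {(lv, pm): [] for lv in fdr_levels for pm in pvalue_modes}
    for rep, child in enumerate(master.spawn(reps)):
        sim_seed, perm_seed = child.spawn(2)
        if mode == "one":
            ds = simulate_one_group(n=n, pi0=pi0, seed=sim_seed)
            fit = sig.fit_one_group(ds.data, fve_threshold=fve_threshold,
                                    bandwidth=bandwidth)
            null = sig.permute_one_group(fit.fpca.centered, fit.fpca.eig,
                                         fit.delta, B, seed=perm_seed)
        else:
            ds = simulate_two_group(n=n, pi0=pi0, seed=sim_seed)
            fit = sig.fit_multi_group(ds.groups, fve_threshold=fve_threshold,
                                      bandwidth=bandwidth)
            if bin_width is None:
                scheme = sig._per_timepoint_scheme(ds.groups)
            else:
                scheme = sig.make_bins(ds.groups, bin_width)
            null = sig.permute_multi_group(fit, scheme, B, seed=perm_seed)
        pvals = {}
        for pm in pvalue_modes:
            if pm == "pooled":
                pvals[pm] = sig.pvalues_pooled(fit.f, null)
            elif pm == "genewise":
                pvals[pm] = sig.pvalues_genewise(fit.f, null)
            else:
                raise ValueError(f"unknown pvalue_mode {pm!r}")
        for (lv, pm), acc in cells.items():
            _, rejected = sig.bh_adjust(pvals[pm], lv)
            acc.append(fpr_sensitivity(rejected, ds.truth))
        logger.debug("rep %d/%d done", rep + 1, reps)
    results = []
    for (lv, pm), acc in cells.items():
        fprs = np.array([a[0] for a in acc])
        sens = np.array([a[1] for a in acc])
        results.append(
            StudyResult(
                mode=mode, pi0=pi0, fdr_level=lv, pvalue_mode=pm, reps=reps,
                fpr_mean=float(fprs.mean()),
                sensitivity_mean=float(np.nanmean(sens)) if np.isfinite(sens).any()
                else float("nan"),
                per_rep=acc, B=B, n=n, seed=seed,
            )
        )
    return results


def study_table(results: list[StudyResult]) -> pd.DataFrame:
    """Tabulate study results, one row per (setting, FDR, p-mode) cell."""
    return pd.DataFrame(
        [
            {
                "mode": r.mode, "pi0": r.pi0, "fdr": r.fdr_level,
                "pvalue_mode": r.pvalue_mode, "reps": r.reps, "n": r.n,
                "B": r.B, "fpr": r.fpr_mean, "sensitivity": r.sensitivity_mean,
            }
            for r in results
        ]
    )
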