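"""Tab-separated readers and writers.

The native expression format is a TSV matrix: cell (1,1) is the literal
``gene``, the rest of the header row holds numeric sampling times, and each
following row is a gene identifier plus its values.  Duplicated time labels
denote replicate columns and are averaged on read (the models operate on
replicate-averaged data); ``NA`` or an empty cell marks a missing value.
"""
from __future__ import annotations

import numpy as np

from .fpca import CovarianceEstimate, EigenSystem, ExpressionMatrix
from .significance import FTestResult

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "write_results_tsv",
    "write_covariance_tsv",
    "write_eigensystem_tsv",
]

_FMT = "%.10g"


def read_expression_tsv(path) -> ExpressionMatrix:
    """Read an expression matrix, averaging replicate columns.

    Raises ValueError with the offending line/column for non-numeric time
    headers, duplicate gene ids, and ragged rows.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split("\t")
    if header[0].strip().lower() != "gene":
        raise ValueError(f"{path}: header cell (1,1) must be 'gene'")
    try:
        raw_times = np.array([float(c) for c in header[1:]])
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric time in header: {exc}") from exc
    n_cols = len(raw_times)
    gene_ids, rows = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != n_cols + 1:
            raise ValueError(
                f"{path}:{lineno}: expected {n_cols + 1} columns, got {len(cells)}"
            )
        gene_ids.append(cells[0])
        row = np.empty(n_cols)
        for ci, cell in enumerate(cells[1:]):
            cell = cell.strip()
            if cell == "" or cell.upper() == "NA":
                row[ci] = np.nan
            else:
                try:
                    row[ci] = float(cell)
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: bad value {cell!r}"
                    ) from exc
        rows.append(row)
    if len(set(gene_ids)) != len(gene_ids):
        seen, dup = set(), None
        for g in gene_ids:
            if g in seen:
                dup = g
                break
            seen.add(g)
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    values = np.array(rows)
    # average replicate columns (duplicated time labels), sort by time
    utimes = np.unique(raw_times)
    averaged = np.empty((len(gene_ids), len(utimes)))
    import warnings

    for ui, t in enumerate(utimes):
        block = values[:, raw_times == t]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NA replicates
            averaged[:, ui] = np.nanmean(block, axis=1)
    return ExpressionMatrix(gene_ids=gene_ids, times=utimes, values=averaged)


def write_expression_tsv(data: ExpressionMatrix, path) -> None:
    """Write an expression matrix in the native TSV layout."""
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(_FMT % t for t in data.times) + "\n")
        for gid, row, obs in zip(data.gene_ids, data.values, data.observed):
            cells = [
                (_FMT % v) if o else "NA" for v, o in zip(row, obs)
            ]
            fh.write(gid + "\t" + "\t".join(cells) + "\n")


def write_covariance_tsv(cov: CovarianceEstimate, path) -> None:
    """Write the smoothed covariance surface (grid x grid) for inspection."""
    with open(path, "w") as fh:
        fh.write(f"# sigma2={_FMT % cov.sigma2}\n")
        fh.write(f"# bandwidth={_FMT % cov.bandwidth}\n")
        fh.write("t\t" + "\t".join(_FMT % t for t in cov.grid) + "\n")
        for t, row in zip(cov.grid, cov.smooth):
            fh.write(_FMT % t + "\t" + "\t".join(_FMT % v for v in row) + "\n")


def write_eigensystem_tsv(eig: EigenSystem, path) -> None:
    """Write eigenvalues, FVE and discretized eigenfunctions for inspection."""
    with open(path, "w") as fh:
        fh.write(f"# L={eig.L}\n")
        header = ["t"] + [f"phi{l + 1}" for l in range(len(eig.eigenvalues))]
        fh.write("# eigenvalues=" + ",".join(_FMT % v for v in eig.eigenvalues) + "\n")
        fh.write("# fve=" + ",".join(_FMT % v for v in eig.fve) + "\n")
        fh.write("\t".join(header) + "\n")
        for k, t in enumerate(eig.grid):
            row = [_FMT % t] + [_FMT % phi[k] for phi in eig.eigenfunctions]
            fh.write("\t".join(row) + "\n")


def write_results_tsv(result: FTestResult, path, metadata: dict | None = None) -> None:
    """Write per-gene test results with '#'-prefixed metadata lines."""
    meta = dict(result.info)
    if metadata:
        meta.update(metadata)
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}={val}\n")
        fh.write("gene\trss0\trss1\tF\tp\tp_adjusted\trejected\n")
        for i, gid in enumerate(result.gene_ids):
            fh.write(
                "\t".join(
                    [
                        gid,
                        _FMT % result.rss0[i],
                        _FMT % result.rss1[i],
                        _FMT % result.f[i],
                        _FMT % result.p[i],
                        _FMT % result.p_adjusted[i],
                        str(bool(result.rejected[i])),
                    ]
                )
                + "\n"
            )
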