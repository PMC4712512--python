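"""Expression preprocessing.

Raw two-channel replicate intensities are turned into the smoothed
differential time courses the decomposition runs on:

1. loess normalization within each time point (intensity-dependent
   log-ratio trend removed, tricube weights, robustified);
2. quantile normalization across all columns (time points, conditions
   and replicates share one reference distribution);
3. per-time-point two-sample t-tests and linear fold changes between
   treatment and control replicate means; a gene is a differentially
   expressed gene (DEG) when |fold change| exceeds 1.5x and p < 0.05 at
   two or more time points;
4. Fourier-series smoothing of each gene's differential time course.

The fold-change rule is two-sided (>1.5 or <1/1.5): repression matters
as much as activation when miRNAs are the regulators of interest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .synthetic import RawMicroarray, TimeGrid

__all__ = [
    "DEGTable",
    "PreprocessResult",
    "loess_normalize_within_timepoint",
    "quantile_normalize",
    "differential_expression",
    "fourier_smooth",
    "preprocess_experiment",
]


def loess_normalize_within_timepoint(
    channel_a: np.ndarray,
    channel_b: np.ndarray,
    span: float = 0.3,
) -> np.ndarray:
    """Loess-correct the log ratio of two intensity channels.

    Computes M = log2(a/b) and A = (log2 a + log2 b)/2, fits a locally
    weighted regression of M on A (tricube weights, the given span,
    2 robustifying iterations) and returns M minus the fitted trend —
    the standard within-array normalization for two-channel arrays.
    """
    a = np.asarray(channel_a, dtype=float)
    b = np.asarray(channel_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("channels must be equal-length vectors")
    if a.size < 10:
        raise ValueError("need at least 10 points to estimate the loess trend")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("intensities must be positive")
    m = np.log2(a / b)
    av = (np.log2(a) + np.log2(b)) / 2.0
    trend = lowess(m, av, frac=span, it=2, return_sorted=False)
    return m - trend


def quantile_normalize(matrix) -> pd.DataFrame | np.ndarray:
    """Force every column onto the common reference distribution.

    The reference is the row-wise mean of the column-sorted matrix; each
    column is mapped onto it by rank, with tied values receiving the
    mean of the reference values at their tied ranks. Idempotent, and
    rank order within every column is preserved.
    """
    is_df = isinstance(matrix, pd.DataFrame)
    x = matrix.to_numpy(dtype=float) if is_df else np.asarray(matrix, dtype=float)
    if np.isnan(x).any():
        raise ValueError("missing values are not supported")
    n = x.shape[0]
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    ranks_grid = np.arange(1, n + 1, dtype=float)
    for j in range(x.shape[1]):
        ranks = stats.rankdata(x[:, j], method="average")
        out[:, j] = np.interp(ranks, ranks_grid, reference)
    if is_df:
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


@dataclass
class DEGTable:
    """Per-gene, per-time-point differential expression calls.

    ``table`` is long-format with columns gene, time, fold_change (linear
    scale, treatment/control), p_value and pass (the per-time-point
    threshold flag); ``selected`` marks genes passing at >= ``min_timepoints``
    time points.
    """

    table: pd.DataFrame
    selected: pd.Series  # bool per gene
    fold_change: pd.DataFrame  # genes x times, linear scale
    p_value: pd.DataFrame  # genes x times

    @property
    def selected_genes(self) -> list[str]:
        return list(self.selected.index[self.selected])


def differential_expression(
    control: np.ndarray,
    treatment: np.ndarray,
    grid: TimeGrid,
    genes: list[str] | None = None,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
    min_timepoints: int = 2,
) -> DEGTable:
    """Two-sample t-tests and fold changes at every time point.

    ``control`` and ``treatment`` are (genes x time points x replicates)
    log2 arrays with >= 2 replicates each. The fold change is the linear
    ratio of replicate means, ``2**(mean_t - mean_c)``; the t-test is
    two-sided with pooled (equal) variance — with two replicates per
    condition a Welch correction would make the degrees of freedom
    unstable. A gene where both groups are constant and equal gets
    p = 1 by convention.
    """
    control = np.asarray(control, dtype=float)
    treatment = np.asarray(treatment, dtype=float)
    if control.ndim != 3 or treatment.ndim != 3:
        raise ValueError("expect genes x timepoints x replicates arrays")
    if control.shape[:2] != treatment.shape[:2]:
        raise ValueError("control/treatment gene or time dimensions differ")
    if control.shape[2] < 2 or treatment.shape[2] < 2:
        raise ValueError("need >= 2 replicates per condition")
    N, M = control.shape[:2]
    if M != len(grid):
        raise ValueError("time dimension does not match the grid")
    genes = list(genes) if genes is not None else [f"g{i}" for i in range(N)]

    fc = np.empty((N, M))
    pv = np.empty((N, M))
    for t in range(M):
        c, tr = control[:, t, :], treatment[:, t, :]
        fc[:, t] = 2.0 ** (tr.mean(axis=1) - c.mean(axis=1))
        with warnings.catch_warnings():
            # near-identical replicate groups trip scipy's moment-precision
            # warning; the degenerate cases are handled explicitly below
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(tr, c, axis=1, equal_var=True)
        p = np.asarray(res.pvalue)
        # both groups constant: p=1 when means agree, p=0 otherwise
        degenerate = np.isnan(p)
        if degenerate.any():
            equal = np.isclose(tr.mean(axis=1), c.mean(axis=1))
            p[degenerate & equal] = 1.0
            p[degenerate & ~equal] = 0.0
        pv[:, t] = p

    passes = ((fc > fc_threshold) | (fc < 1.0 / fc_threshold)) & (pv < p_threshold)
    selected = pd.Series(passes.sum(axis=1) >= min_timepoints, index=genes)
    times = list(grid.times)
    long = pd.DataFrame(
        {
            "gene": np.repeat(genes, M),
            "time": np.tile(times, N),
            "fold_change": fc.ravel(),
            "p_value": pv.ravel(),
            "pass": passes.ravel(),
        }
    )
    return DEGTable(
        table=long,
        selected=selected,
        fold_change=pd.DataFrame(fc, index=genes, columns=times),
        p_value=pd.DataFrame(pv, index=genes, columns=times),
    )


def fourier_design(grid: TimeGrid, n_harmonics: int) -> np.ndarray:
    """Design matrix [1, cos(2πkt/P), sin(2πkt/P)] for k = 1..n_harmonics."""
    t = grid.array - grid.times[0]
    period = grid.span
    cols = [np.ones_like(t)]
    for k in range(1, n_harmonics + 1):
        cols.append(np.cos(2 * np.pi * k * t / period))
        cols.append(np.sin(2 * np.pi * k * t / period))
    return np.column_stack(cols)


def fourier_smooth(series, grid: TimeGrid, n_harmonics: int = 4) -> np.ndarray:
    """Least-squares truncated Fourier fit, evaluated back on the grid.

    ``series`` may be a vector or a (genes x time points) matrix. The
    period is the grid span. Requires ``n_harmonics < (M - 1) / 2`` so
    the fit does not interpolate the noise.
    """
    y = np.asarray(series, dtype=float)
    squeeze = y.ndim == 1
    y2 = np.atleast_2d(y)
    if y2.shape[1] != len(grid):
        raise ValueError("series length does not match the grid")
    if n_harmonics >= (len(grid) - 1) / 2:
        raise ValueError(
            f"n_harmonics={n_harmonics} over-parameterized for {len(grid)} points"
        )
    X = fourier_design(grid, n_harmonics)
    coef, *_ = np.linalg.lstsq(X, y2.T, rcond=None)
    fit = (X @ coef).T
    return fit[0] if squeeze else fit


@dataclass
class PreprocessResult:
    """Normalized, averaged and smoothed view of a raw experiment."""

    genes: list[str]
    grid: TimeGrid
    control: pd.DataFrame  # genes x times, replicate-averaged log2
    treatment: pd.DataFrame
    differential: pd.DataFrame  # treatment - control, log2
    smoothed: pd.DataFrame  # Fourier-smoothed differential
    degs: DEGTable


def preprocess_experiment(
    raw: RawMicroarray,
    span: float = 0.3,
    n_harmonics: int = 4,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
    min_timepoints: int = 2,
) -> PreprocessResult:
    """Full preprocessing chain on a raw two-channel experiment.

    Within each time point and replicate, the treatment/control log
    ratio is loess-corrected and the two channels reconstructed
    symmetrically around their mean intensity. All columns are then
    quantile-normalized together, differential expression is tested on
    the normalized replicates, replicates are averaged (after
    normalization), and the differential time course is smoothed.
    """
    N, M, R = raw.control.shape
    ctrl = np.empty_like(raw.control)
    trt = np.empty_like(raw.treatment)
    for t in range(M):
        for r in range(R):
            a = 2.0 ** raw.treatment[:, t, r]
            b = 2.0 ** raw.control[:, t, r]
            m_corr = loess_normalize_within_timepoint(a, b, span=span)
            av = (np.log2(a) + np.log2(b)) / 2.0
            trt[:, t, r] = av + m_corr / 2.0
            ctrl[:, t, r] = av - m_corr / 2.0

    stacked = np.concatenate(
        [ctrl.reshape(N, M * R), trt.reshape(N, M * R)], axis=1
    )
    normed = quantile_normalize(stacked)
    ctrl = normed[:, : M * R].reshape(N, M, R)
    trt = normed[:, M * R :].reshape(N, M, R)

    degs = differential_expression(
        ctrl,
        trt,
        raw.grid,
        genes=raw.genes,
        fc_threshold=fc_threshold,
        p_threshold=p_threshold,
        min_timepoints=min_timepoints,
    )
    times = list(raw.grid.times)
    control_avg = pd.DataFrame(ctrl.mean(axis=2), index=raw.genes, columns=times)
    treatment_avg = pd.DataFrame(trt.mean(axis=2), index=raw.genes, columns=times)
    differential = treatment_avg - control_avg
    smoothed = pd.DataFrame(
        fourier_smooth(differential.to_numpy(), raw.grid, n_harmonics=n_harmonics),
        index=raw.genes,
        columns=times,
    )
    return PreprocessResult(
        genes=list(raw.genes),
        grid=raw.grid,
        control=control_avg,
        treatment=treatment_avg,
        differential=differential,
        smoothed=smoothed,
        degs=degs,
    )
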