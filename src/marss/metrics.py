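"""Slice-wise timeseries metrics and the simultaneous-slice artifact statistic.

The detection statistic r_U-Y compares, for each slice j, the mean Pearson
correlation of its (motion-residualized) slice-mean timeseries with those
of its simultaneous-acquisition partners U_j against the mean correlation
with the adjacent-to-simultaneous slices Y_j directly above and below the
members of U_j. Correlations are Fisher z-transformed before averaging or
subtracting and transformed back to r for reporting. Under the null of no
shared simultaneous-slice signal the statistic is ~0, because adjacent
slices share at least as much anatomy and smoothness as slices a third of
the volume away.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._linalg import ols_fit
from .data import BoldRun, NuisanceMatrix, SliceSetPartition

__all__ = [
    "SliceTimeseriesMatrix",
    "SliceCorrReport",
    "slice_mean_timeseries",
    "residualize",
    "slice_correlation_matrix",
    "r_U_minus_Y",
    "detect",
    "compare_runs_signed_rank",
]

#: |r| at or above this is treated as a degenerate (duplicate-slice) pair
#: whose Fisher z would diverge; such pairs are excluded with a warning.
_R_DEGENERATE = 1.0 - 1e-12


@dataclass
class SliceTimeseriesMatrix:
    """Ns x T matrix of slice-mean signals, with zero-variance rows flagged."""

    X: np.ndarray
    residualized: bool = False
    mask_used: str | None = None
    zero_variance: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2:
            raise ValueError("slice timeseries matrix must be 2D (slices x time)")
        if self.zero_variance is None:
            self.zero_variance = np.var(self.X, axis=1) == 0
        else:
            self.zero_variance = np.asarray(self.zero_variance, dtype=bool)

    @property
    def n_slices(self) -> int:
        return self.X.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.X.shape[1]


@dataclass
class SliceCorrReport:
    """Slice-pair correlation matrix and the r_U-Y summary statistic."""

    R: np.ndarray
    r_simul: float
    r_adjacent: float
    r_U_minus_Y: float
    n_pairs_simul: int
    n_pairs_adjacent: int
    n_pairs_excluded: int = 0


def slice_mean_timeseries(run: BoldRun, mask: np.ndarray | None = None) -> SliceTimeseriesMatrix:
    """Mean timeseries of every slice, optionally restricted to a binary mask.

    Slices with no included voxels yield flagged zero rows instead of NaNs.
    """
    vol = run.slices_last()
    ns, T = run.n_slices, run.n_volumes
    if mask is not None:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != run.spatial_shape:
            raise ValueError(
                f"mask shape {mask.shape} does not match data {run.spatial_shape}"
            )
        m = np.moveaxis(mask, run.slice_axis, 2)
        X = np.zeros((ns, T))
        for j in range(ns):
            sel = m[:, :, j]
            if sel.any():
                X[j] = vol[:, :, j, :][sel].mean(axis=0, dtype=np.float64)
    else:
        X = vol.mean(axis=(0, 1), dtype=np.float64).reshape(ns, T)
    return SliceTimeseriesMatrix(X=X, mask_used=None if mask is None else "mask")


def residualize(X: SliceTimeseriesMatrix, M: NuisanceMatrix) -> SliceTimeseriesMatrix:
    """Residualize each slice timeseries on an intercept plus the nuisance matrix.

    Rank-deficient designs are handled by the pseudoinverse (minimum-norm)
    solution; a dimension mismatch is an error.
    """
    if M.n_volumes != X.n_volumes:
        raise ValueError(
            f"nuisance matrix has {M.n_volumes} rows but timeseries has {X.n_volumes}"
        )
    design = np.column_stack([np.ones(M.n_volumes), M.M])
    _, resid = ols_fit(design, X.X.T, context="slice residualization")
    return SliceTimeseriesMatrix(
        X=resid.T,
        residualized=True,
        mask_used=X.mask_used,
        zero_variance=X.zero_variance.copy(),
    )


def slice_correlation_matrix(X: SliceTimeseriesMatrix) -> np.ndarray:
    """Full symmetric Pearson matrix between slice timeseries.

    Zero-variance rows produce NaN entries, which downstream averages skip.
    """
    if X.n_volumes < 3:
        raise ValueError("need at least 3 timepoints for slice correlations")
    valid = ~X.zero_variance & (np.var(X.X, axis=1) > 0)
    R = np.full((X.n_slices, X.n_slices), np.nan)
    if valid.sum() >= 1:
        sub = np.corrcoef(X.X[valid])
        sub = np.atleast_2d(sub)
        idx = np.flatnonzero(valid)
        R[np.ix_(idx, idx)] = sub
    np.fill_diagonal(R, np.where(valid, 1.0, np.nan))
    return R


def _fisher_mean(R: np.ndarray, pairs: list[tuple[int, int]]) -> tuple[float, int, int]:
    """Mean Fisher z over ordered slice pairs; returns (z_mean, n_used, n_excluded)."""
    zs = []
    excluded = 0
    for j, k in pairs:
        r = R[j, k]
        if not np.isfinite(r):
            excluded += 1
            continue
        if abs(r) >= _R_DEGENERATE:
            excluded += 1
            continue
        zs.append(np.arctanh(r))
    if excluded:
        warnings.warn(
            f"{excluded} degenerate or undefined slice pairs excluded from the "
            "correlation averages",
            stacklevel=3,
        )
    if not zs:
        return np.nan, 0, excluded
    return float(np.mean(zs)), len(zs), excluded


def r_U_minus_Y(R: np.ndarray, part: SliceSetPartition) -> SliceCorrReport:
    """The simultaneous-minus-adjacent slice correlation statistic.

    Averages Fisher z over all ordered pairs (j, k in U_j, k != j) and over
    all ordered pairs (j, k in Y_j), subtracts the means, and transforms
    back to r: tanh(z_U - z_Y). Self-pairs are excluded (their z diverges).
    """
    R = np.asarray(R, dtype=np.float64)
    if R.shape[0] != part.n_slices:
        raise ValueError("correlation matrix size does not match the partition")
    simul_pairs = [
        (j - 1, k - 1)
        for j in range(1, part.n_slices + 1)
        for k in part.simultaneous_of[j]
        if k != j
    ]
    adj_pairs = [
        (j - 1, k - 1)
        for j in range(1, part.n_slices + 1)
        for k in part.adjacent_of[j]
    ]
    z_u, n_u, ex_u = _fisher_mean(R, simul_pairs)
    z_y, n_y, ex_y = _fisher_mean(R, adj_pairs)
    return SliceCorrReport(
        R=R,
        r_simul=float(np.tanh(z_u)),
        r_adjacent=float(np.tanh(z_y)),
        r_U_minus_Y=float(np.tanh(z_u - z_y)),
        n_pairs_simul=n_u,
        n_pairs_adjacent=n_y,
        n_pairs_excluded=ex_u + ex_y,
    )


def detect(
    run: BoldRun,
    part: SliceSetPartition,
    nuisance: NuisanceMatrix | None = None,
    mask: np.ndarray | None = None,
) -> SliceCorrReport:
    """One-call artifact detection: slice means -> residualize -> correlate -> r_U-Y."""
    X = slice_mean_timeseries(run, mask=mask)
    if nuisance is not None:
        X = residualize(X, nuisance)
    R = slice_correlation_matrix(X)
    return r_U_minus_Y(R, part)


def compare_runs_signed_rank(
    stat_pre: np.ndarray, stat_post: np.ndarray
) -> dict[str, float]:
    """Two-sided Wilcoxon signed-rank test on paired per-run statistics.

    Uses the exact null distribution up to n = 25 nonzero differences and
    the normal approximation with continuity correction beyond that.
    Returns ``{"W": ..., "p": ..., "n": ...}``.
    """
    pre = np.asarray(stat_pre, dtype=np.float64)
    post = np.asarray(stat_post, dtype=np.float64)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("paired statistics must be equal-length 1D sequences")
    if pre.size < 5:
        raise ValueError("need at least 5 paired runs for the signed-rank test")
    diffs = pre - post
    nz = np.count_nonzero(diffs)
    if nz == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return {"W": 0.0, "p": 1.0, "n": 0}
    method = "exact" if nz <= 25 else "approx"
    res = stats.wilcoxon(
        pre, post, zero_method="wilcox", correction=(method == "approx"), method=method
    )
    return {"W": float(res.statistic), "p": float(res.pvalue), "n": int(nz)}
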