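"""MARSS: estimation and voxelwise removal of the shared simultaneous-slice artifact.

The method is a two-stage regression. Stage one estimates, for each slice
j, a single artifact timeseries a_j: the mean timeseries of all voxels in
the slices acquired simultaneously with j (excluding j itself) is
residualized on an intercept, the global mean of all *non*-simultaneous
slices, and the 24-parameter motion nuisance expansion; the residual is
a_j. Stage two regresses every voxel timeseries in slice j on
[1, a_j, g_Uj, M] and subtracts the fitted a_j component, so that exactly
one degree of freedom (the artifact direction) is removed per voxel.

Two estimation variants restrict the voxels that contribute to the
stage-one average: ``background_only`` uses only voxels outside a
(1-voxel-dilated) brain mask, and ``thresholded`` runs a first standard
pass, keeps the top p% of voxels per slice by artifact magnitude, and
re-estimates from those voxels alone (MARSS30/20/10 for p = 30/20/10).

The public surface follows the statsmodels convention: build a
:class:`MARSS` model from a run, call :meth:`MARSS.fit`, and read
estimates, diagnostics and the summary table off the returned
:class:`MARSSResults`.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._linalg import check_condition, ols_fit
from .data import (
    BoldRun,
    MotionParams,
    NuisanceMatrix,
    SliceSetPartition,
    expand_motion,
    load_bold,
    load_motion,
    save_bold,
    slice_partition,
)
from .metrics import SliceCorrReport, detect

__all__ = [
    "ArtifactEstimate",
    "MARSS",
    "MARSSResults",
    "simultaneous_mean",
    "nonsimultaneous_global",
    "estimate_artifact",
    "remove_artifact",
    "magnitude_map",
    "percent_magnitude_map",
    "run_marss",
]


@dataclass
class ArtifactEstimate:
    """Per-slice and per-voxel artifact signal estimated by MARSS.

    ``a`` holds the slice-level artifact timeseries (Ns x T); after
    removal, ``beta_maps`` holds each voxel's loading on its slice's a_j,
    ``artifact_4d`` the voxelwise artifact timeseries beta * a_j, and
    ``magnitude`` its temporal mean absolute value. ``g`` caches the
    non-simultaneous global regressor per slice.
    """

    a: np.ndarray
    g: np.ndarray
    variant: str = "standard"
    threshold_percent: float | None = None
    beta_maps: np.ndarray | None = None
    artifact_4d: np.ndarray | None = None
    magnitude: np.ndarray | None = None
    weights: np.ndarray | None = None


def _slice_sums(run: BoldRun, weights: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    """Per-slice (weighted) voxel sums over time and (weighted) voxel counts.

    Returns (sums: Ns x T, counts: Ns).
    """
    vol = run.slices_last()
    ns, T = run.n_slices, run.n_volumes
    if weights is None:
        sums = vol.sum(axis=(0, 1), dtype=np.float64).reshape(ns, T)
        counts = np.full(ns, vol.shape[0] * vol.shape[1], dtype=np.float64)
    else:
        w = np.asarray(weights, dtype=np.float64)
        if w.shape != run.spatial_shape:
            raise ValueError("weights shape must match the spatial shape")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        wv = np.moveaxis(w, run.slice_axis, 2)
        sums = np.einsum("xys,xyst->st", wv, vol, dtype=np.float64)
        counts = wv.sum(axis=(0, 1))
    return sums, counts


def simultaneous_mean(
    run: BoldRun,
    part: SliceSetPartition,
    j: int,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Mean timeseries over all voxels of the slices simultaneous to j, excluding j.

    With ``weights`` (nonnegative, typically binary), the weighted average
    of the contributing voxel timeseries is returned instead; uniform
    weights reduce exactly to the unweighted mean.
    """
    sums, counts = _slice_sums(run, weights)
    partners = [u for u in part.simultaneous_of[j] if u != j]
    total = counts[[u - 1 for u in partners]].sum()
    if total <= 0:
        raise ValueError(
            f"no contributing voxels for slice {j}: every partner slice has zero weight"
        )
    return sums[[u - 1 for u in partners]].sum(axis=0) / total


def nonsimultaneous_global(
    run: BoldRun, part: SliceSetPartition, j: int
) -> np.ndarray:
    """Mean timeseries over all voxels of slices *not* simultaneous to j."""
    if run.n_slices <= part.mb_factor:
        raise ValueError("no non-simultaneous slices: Ns equals the multiband factor")
    sums, counts = _slice_sums(run, None)
    others = [u for u in range(1, run.n_slices + 1) if u not in part.simultaneous_of[j]]
    idx = [u - 1 for u in others]
    return sums[idx].sum(axis=0) / counts[idx].sum()


def estimate_artifact(
    run: BoldRun,
    part: SliceSetPartition,
    nuisance: NuisanceMatrix | None = None,
    weights: np.ndarray | None = None,
    variant: str = "standard",
    threshold_percent: float | None = None,
) -> ArtifactEstimate:
    """Stage one: per-slice artifact timeseries a_j.

    For each slice j the simultaneous-partner mean s_j is residualized on
    the design [1, g_Uj, M] (26 columns with the 24-column motion
    expansion); the residual is a_j, orthogonal by construction to the
    intercept, the non-simultaneous global signal, and motion.
    """
    ns, T = run.n_slices, run.n_volumes
    if nuisance is not None and nuisance.n_volumes != T:
        raise ValueError("nuisance matrix row count does not match the run length")
    M = nuisance.M if nuisance is not None else np.empty((T, 0))
    a = np.zeros((ns, T))
    g = np.zeros((ns, T))
    if ns <= part.mb_factor:
        raise ValueError("no non-simultaneous slices: Ns equals the multiband factor")
    full_sums, full_counts = _slice_sums(run, None)
    w_sums, w_counts = (
        (full_sums, full_counts) if weights is None else _slice_sums(run, weights)
    )
    # g_Uj is identical for every slice of a set; compute once per set
    g_of_set: dict[tuple[int, ...], np.ndarray] = {}
    for s in part.sets:
        others = [u - 1 for u in range(1, ns + 1) if u not in s]
        g_of_set[s] = full_sums[others].sum(axis=0) / full_counts[others].sum()
    for j in range(1, ns + 1):
        partners = [u - 1 for u in part.simultaneous_of[j] if u != j]
        total = w_counts[partners].sum()
        if total <= 0:
            raise ValueError(
                f"no contributing voxels for slice {j}: every partner slice has zero weight"
            )
        s_j = w_sums[partners].sum(axis=0) / total
        g_j = g_of_set[part.simultaneous_of[j]]
        design = np.column_stack([np.ones(T), g_j, M])
        _, resid = ols_fit(design, s_j, context=f"artifact estimation, slice {j}")
        a[j - 1] = resid
        g[j - 1] = g_j
    return ArtifactEstimate(
        a=a,
        g=g,
        variant=variant,
        threshold_percent=threshold_percent,
        weights=None if weights is None else np.asarray(weights, dtype=np.float64),
    )


def remove_artifact(
    run: BoldRun,
    est: ArtifactEstimate,
    part: SliceSetPartition,
    nuisance: NuisanceMatrix | None = None,
) -> tuple[BoldRun, ArtifactEstimate]:
    """Stage two: fit and subtract each voxel's loading on its slice artifact.

    Per voxel i of slice j the design is [1, a_j, g_Uj, M]; only the fitted
    a_j component (coefficient times a_j) is subtracted, so the corrected
    data plus the voxelwise artifact reconstruct the input exactly.
    """
    ns, T = run.n_slices, run.n_volumes
    M = nuisance.M if nuisance is not None else np.empty((T, 0))
    vol = run.slices_last()
    corrected = np.empty_like(vol)
    artifact = np.empty_like(vol)
    betas = np.zeros(vol.shape[:3])
    magnitude = np.zeros(vol.shape[:3])
    shp = vol.shape[:2]
    for j in range(1, ns + 1):
        a_j = est.a[j - 1]
        g_j = est.g[j - 1]
        design = np.column_stack([np.ones(T), a_j, g_j, M])
        check_condition(design, context=f"artifact removal, slice {j}")
        pinv = np.linalg.pinv(design)  # n_regressors x T
        D = vol[:, :, j - 1, :].reshape(-1, T)  # Nv x T
        beta_a = pinv[1] @ D.T  # loading on the a_j column, per voxel
        art = beta_a[:, None] * a_j[None, :]  # Nv x T
        if artifact.dtype != art.dtype:
            art = art.astype(artifact.dtype)
        art3 = art.reshape(*shp, T)
        artifact[:, :, j - 1, :] = art3
        np.subtract(vol[:, :, j - 1, :], art3, out=corrected[:, :, j - 1, :])
        betas[:, :, j - 1] = beta_a.reshape(shp)
        magnitude[:, :, j - 1] = np.abs(art).mean(axis=1).reshape(shp)
    est.beta_maps = np.moveaxis(betas, 2, run.slice_axis)
    est.artifact_4d = np.moveaxis(artifact, 2, run.slice_axis)
    est.magnitude = np.moveaxis(magnitude, 2, run.slice_axis)
    out = run.with_data(np.moveaxis(corrected, 2, run.slice_axis))
    return out, est


def magnitude_map(est: ArtifactEstimate) -> np.ndarray:
    """Spatial artifact magnitude A: temporal mean of |voxelwise artifact|."""
    if est.artifact_4d is None:
        raise ValueError("voxelwise artifact not computed yet; run remove_artifact first")
    return np.abs(est.artifact_4d).mean(axis=3)


def percent_magnitude_map(
    est: ArtifactEstimate, run: BoldRun, min_mean: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Artifact magnitude as a percentage of mean voxel intensity.

    Voxels whose temporal mean falls below ``min_mean`` (default: 1e-3 of
    the maximum mean intensity) are excluded (NaN) and flagged in the
    returned boolean mask.
    """
    A = magnitude_map(est) if est.magnitude is None else est.magnitude
    mean_img = run.data.mean(axis=3, dtype=np.float64)
    if min_mean is None:
        min_mean = 1e-3 * float(np.abs(mean_img).max())
    ok = np.abs(mean_img) > min_mean
    pct = np.full_like(A, np.nan)
    pct[ok] = 100.0 * A[ok] / mean_img[ok]
    return pct, ok


def _background_weights(brain_mask: np.ndarray, slice_axis: int) -> np.ndarray:
    """Binary weights selecting voxels outside the 1-voxel-dilated brain mask."""
    mask = np.asarray(brain_mask).astype(bool)
    dilated = ndimage.binary_dilation(
        mask, structure=ndimage.generate_binary_structure(3, 1)
    )
    return (~dilated).astype(np.float64)


def _threshold_weights(
    magnitude: np.ndarray, slice_axis: int, percent: float
) -> np.ndarray:
    """Binary weights keeping, per slice, the top ``percent``% of voxels by magnitude."""
    mag = np.moveaxis(magnitude, slice_axis, 2)
    w = np.zeros_like(mag)
    for j in range(mag.shape[2]):
        sl = mag[:, :, j]
        thr = np.percentile(sl, 100.0 - percent)
        w[:, :, j] = sl >= thr
    return np.moveaxis(w, 2, slice_axis)


class MARSS:
    """Multiband artifact regression model for one BOLD run.

    Parameters
    ----------
    run : BoldRun
        The uncorrected 4D run.
    mb_factor : int
        Multiband (simultaneous multi-slice) acceleration factor.
    motion : MotionParams, optional
        Volume-wise rigid-body motion; expanded to the 24-column nuisance
        set. Without it the nuisance block is empty (intercept and global
        signal only).
    variant : {"standard", "background_only", "thresholded"}
        Estimation variant; ``background_only`` requires ``brain_mask``,
        ``thresholded`` requires ``threshold_percent``.
    brain_mask : ndarray, optional
        Binary brain mask, used by the background-only variant and by
        mask-restricted diagnostics.
    """

    def __init__(
        self,
        run: BoldRun,
        mb_factor: int,
        motion: MotionParams | None = None,
        variant: str = "standard",
        brain_mask: np.ndarray | None = None,
        threshold_percent: float | None = None,
    ) -> None:
        if variant not in ("standard", "background_only", "thresholded"):
            raise ValueError(f"unknown variant {variant!r}")
        if variant == "background_only" and brain_mask is None:
            raise ValueError("background_only variant requires a brain mask")
        if variant == "thresholded" and not threshold_percent:
            raise ValueError("thresholded variant requires threshold_percent (e.g. 30)")
        if motion is not None and motion.n_volumes != run.n_volumes:
            raise ValueError(
                f"motion has {motion.n_volumes} rows but the run has {run.n_volumes} volumes"
            )
        self.run = run
        self.partition = slice_partition(run.n_slices, mb_factor)
        self.motion = motion
        self.nuisance = expand_motion(motion) if motion is not None else None
        self.variant = variant
        self.brain_mask = None if brain_mask is None else np.asarray(brain_mask).astype(bool)
        self.threshold_percent = threshold_percent

    @classmethod
    def from_files(
        cls,
        bold_path: str | os.PathLike,
        mb_factor: int,
        motion_path: str | os.PathLike | None = None,
        motion_dialect: str = "spm6",
        slice_axis: int = 2,
        **kwargs,
    ) -> "MARSS":
        run = load_bold(bold_path, slice_axis=slice_axis)
        motion = load_motion(motion_path, motion_dialect) if motion_path else None
        return cls(run, mb_factor, motion=motion, **kwargs)

    def _estimation_weights(self) -> np.ndarray | None:
        if self.variant == "background_only":
            return _background_weights(self.brain_mask, self.run.slice_axis)
        return None

    def fit(self) -> "MARSSResults":
        """Run detection, estimation, removal, and re-detection."""
        report_pre = detect(self.run, self.partition, self.nuisance)
        weights = self._estimation_weights()
        if self.variant == "thresholded":
            first = estimate_artifact(self.run, self.partition, self.nuisance)
            _, first = remove_artifact(self.run, first, self.partition, self.nuisance)
            weights = _threshold_weights(
                first.magnitude, self.run.slice_axis, self.threshold_percent
            )
        est = estimate_artifact(
            self.run,
            self.partition,
            self.nuisance,
            weights=weights,
            variant=self.variant,
            threshold_percent=self.threshold_percent,
        )
        corrected, est = remove_artifact(self.run, est, self.partition, self.nuisance)
        report_post = detect(corrected, self.partition, self.nuisance)
        return MARSSResults(
            model=self,
            corrected=corrected,
            estimate=est,
            report_pre=report_pre,
            report_post=report_post,
        )


@dataclass
class MARSSResults:
    """Fitted MARSS correction: corrected run, artifact estimate, pre/post reports."""

    model: MARSS
    corrected: BoldRun
    estimate: ArtifactEstimate
    report_pre: SliceCorrReport
    report_post: SliceCorrReport

    @property
    def artifact_run(self) -> BoldRun:
        """The removed voxelwise artifact as a BoldRun (original = corrected + this)."""
        return self.model.run.with_data(self.estimate.artifact_4d)

    def reduction(self) -> float:
        """Change in the r_U-Y statistic achieved by correction (post minus pre)."""
        return self.report_post.r_U_minus_Y - self.report_pre.r_U_minus_Y

    def to_report_dict(self) -> dict:
        part = self.model.partition
        return {
            "variant": self.model.variant,
            "threshold_percent": self.model.threshold_percent,
            "mb_factor": part.mb_factor,
            "n_slices": part.n_slices,
            "n_simultaneous_sets": part.n_sets,
            "n_volumes": self.model.run.n_volumes,
            "r_U_minus_Y_pre": self.report_pre.r_U_minus_Y,
            "r_U_minus_Y_post": self.report_post.r_U_minus_Y,
            "r_simul_pre": self.report_pre.r_simul,
            "r_simul_post": self.report_post.r_simul,
            "r_adjacent_pre": self.report_pre.r_adjacent,
            "r_adjacent_post": self.report_post.r_adjacent,
        }

    def summary(self) -> str:
        d = self.to_report_dict()
        lines = [
            "MARSS correction results",
            "=" * 48,
            f"{'variant':<28}{d['variant']}"
            + (f" (top {d['threshold_percent']:g}%)" if d["threshold_percent"] else ""),
            f"{'slices / MB factor / sets':<28}{d['n_slices']} / {d['mb_factor']} / {d['n_simultaneous_sets']}",
            f"{'volumes':<28}{d['n_volumes']}",
            "-" * 48,
            f"{'r_U-Y pre-correction':<28}{d['r_U_minus_Y_pre']:+.4f}",
            f"{'r_U-Y post-correction':<28}{d['r_U_minus_Y_post']:+.4f}",
            f"{'simultaneous r pre/post':<28}{d['r_simul_pre']:+.4f} / {d['r_simul_post']:+.4f}",
            f"{'adjacent r pre/post':<28}{d['r_adjacent_pre']:+.4f} / {d['r_adjacent_post']:+.4f}",
            "=" * 48,
        ]
        return "\n".join(lines)

    def save(self, outdir: str | os.PathLike, force: bool = False) -> dict[str, str]:
        """Write corrected/artifact NIFTIs, magnitude maps, CSVs and the JSON report."""
        import pandas as pd

        outdir = str(outdir)
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "corrected": os.path.join(outdir, "corrected.nii.gz"),
            "artifact": os.path.join(outdir, "artifact.nii.gz"),
            "magnitude": os.path.join(outdir, "artifact_magnitude.nii.gz"),
            "percent": os.path.join(outdir, "artifact_percent.nii.gz"),
            "timeseries": os.path.join(outdir, "artifact_timeseries.csv"),
            "corr_pre": os.path.join(outdir, "slice_corr_pre.csv"),
            "corr_post": os.path.join(outdir, "slice_corr_post.csv"),
            "report": os.path.join(outdir, "marss_report.json"),
        }
        if not force:
            for p in paths.values():
                if os.path.exists(p):
                    raise FileExistsError(f"{p} exists; pass force=True to overwrite")
        run = self.model.run
        save_bold(self.corrected, paths["corrected"])
        save_bold(self.artifact_run, paths["artifact"])
        affine = run.affine if run.affine is not None else np.eye(4)
        import nibabel as nib

        nib.save(
            nib.Nifti1Image(self.estimate.magnitude.astype(np.float32), affine),
            paths["magnitude"],
        )
        pct, _ = percent_magnitude_map(self.estimate, run)
        nib.save(nib.Nifti1Image(pct.astype(np.float32), affine), paths["percent"])
        ts = pd.DataFrame(
            self.estimate.a,
            index=[f"slice_{j}" for j in range(1, run.n_slices + 1)],
        )
        ts.to_csv(paths["timeseries"], index_label="slice")
        labels = [f"slice_{j}" for j in range(1, run.n_slices + 1)]
        pd.DataFrame(self.report_pre.R, index=labels, columns=labels).to_csv(paths["corr_pre"])
        pd.DataFrame(self.report_post.R, index=labels, columns=labels).to_csv(paths["corr_post"])
        with open(paths["report"], "w") as fh:
            json.dump(self.to_report_dict(), fh, indent=2)
        return paths


def run_marss(
    run: BoldRun,
    mb_factor: int,
    motion: MotionParams | None = None,
    variant: str = "standard",
    brain_mask: np.ndarray | None = None,
    threshold_percent: float | None = None,
) -> MARSSResults:
    """Functional entry point: build a :class:`MARSS` model and fit it."""
    return MARSS(
        run,
        mb_factor,
        motion=motion,
        variant=variant,
        brain_mask=brain_mask,
        threshold_percent=threshold_percent,
    ).fit()
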