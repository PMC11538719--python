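"""Interslice-leakage analysis for multiband reconstructions.

Controlled-aliasing (CAIPIRINHA) acquisitions shift simultaneous slices
in-plane by a fixed fraction of the field of view before they are
superimposed; imperfect unmixing can leave residual shared signal between
the voxel pairs that were stacked. This module builds the stacked-voxel
correspondence map, removes leakage by per-voxel regression on the stacked
partners (deliberately destructive to true signal — a probe, not a
denoiser), and computes the mean voxel-pair correlation between
simultaneous slices as a function of the in-plane phase shift. The shared
simultaneous-slice artifact removed by MARSS lives in whole slices, not in
stacked voxel pairs, and the two analyses here demonstrate that
independence.

Conventions: a slice at position m (1-based, by ascending slice index)
within its simultaneous set carries shift s_m = (m-1) * round(N_pe /
denominator) voxels along the phase-encode axis, modulo N_pe. The stacked
partner of voxel (x, y) of a slice with shift s, in a slice with shift s',
is (x, (y + s - s') mod N_pe).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import BoldRun, SliceSetPartition

__all__ = [
    "OverlapMap",
    "build_overlap_map",
    "leakage_regression",
    "shiftwise_correlations",
]


@dataclass
class OverlapMap:
    """Stacked-voxel correspondence for a CAIPI-shifted multiband acquisition."""

    partition: SliceSetPartition
    phase_axis: int
    n_pe: int
    base_shift: int
    #: in-plane shift (voxels, modulo n_pe) of each within-set position 1..MBf
    shift_voxels: tuple[int, ...]

    def shift_of_slice(self, j: int) -> int:
        """Acquisition shift of 1-based slice j."""
        pos = self.partition.simultaneous_of[j].index(j)
        return self.shift_voxels[pos]

    def partners(self, j: int) -> list[tuple[int, int]]:
        """For slice j: list of (partner slice, relative shift delta).

        The stacked partner of voxel (x, y) in slice j, within partner
        slice u, sits at (x, (y + delta) mod N_pe). Each voxel has exactly
        MBf - 1 partners.
        """
        s_j = self.shift_of_slice(j)
        out = []
        for u in self.partition.simultaneous_of[j]:
            if u == j:
                continue
            delta = (s_j - self.shift_of_slice(u)) % self.n_pe
            out.append((u, delta))
        return out


def build_overlap_map(
    run: BoldRun,
    part: SliceSetPartition,
    shift_fraction_denominator: int,
    phase_axis: int = 1,
) -> OverlapMap:
    """Construct the stacked-voxel map for a FOV/denominator CAIPI shift.

    The per-position shift is round(N_pe / denominator) voxels; a
    denominator larger than the matrix gives shift 0 (all partners at the
    same in-plane coordinate).
    """
    if shift_fraction_denominator < 2:
        raise ValueError("shift fraction denominator must be >= 2")
    if phase_axis == run.slice_axis or phase_axis not in (0, 1, 2):
        raise ValueError("phase axis must be an in-plane spatial axis")
    n_pe = run.data.shape[phase_axis]
    base = int(round(n_pe / shift_fraction_denominator)) % n_pe
    shifts = tuple((m * base) % n_pe for m in range(part.mb_factor))
    return OverlapMap(
        partition=part,
        phase_axis=phase_axis,
        n_pe=n_pe,
        base_shift=base,
        shift_voxels=shifts,
    )


def _canonical(run: BoldRun, phase_axis: int) -> tuple[np.ndarray, int]:
    """Data as (other, phase, slice, time) and the effective phase axis index."""
    vol = np.moveaxis(run.data, run.slice_axis, 2)
    # phase axis position after moving the slice axis to 2
    axes = [a for a in range(3) if a != run.slice_axis]
    pa = axes.index(phase_axis)
    if pa == 0:
        vol = vol.swapaxes(0, 1)
    return vol, 1


def leakage_regression(run: BoldRun, omap: OverlapMap) -> BoldRun:
    """Regress the stacked-partner timeseries out of every voxel.

    Per voxel: OLS on an intercept plus the MBf - 1 stacked partner
    timeseries; the output is the residual. Constant partner series
    contribute nothing (flagged with a warning).
    """
    part = omap.partition
    if part.n_slices != run.n_slices:
        raise ValueError("overlap map does not match the run")
    vol, _ = _canonical(run, omap.phase_axis)
    na, npe, ns, T = vol.shape
    out = np.array(vol, copy=True)
    n_constant = 0
    for j in range(1, ns + 1):
        D = vol[:, :, j - 1, :]  # na x npe x T
        regs = []
        for u, delta in omap.partners(j):
            # partner_array[x, y] = partner_slice[x, (y + delta) % npe]
            P = np.roll(vol[:, :, u - 1, :], -delta, axis=1)
            const = P.std(axis=2) == 0
            if const.any():
                n_constant += int(const.sum())
                P = P.copy()
                P[const] = 0.0
            regs.append(P)
        G = np.stack(regs, axis=2)  # na x npe x k x T
        Gc = G - G.mean(axis=3, keepdims=True)
        Dc = D - D.mean(axis=2, keepdims=True)
        gram = np.einsum("xykt,xylt->xykl", Gc, Gc)
        rhs = np.einsum("xykt,xyt->xyk", Gc, Dc)
        coef = np.einsum("xykl,xyl->xyk", np.linalg.pinv(gram), rhs)
        out[:, :, j - 1, :] = Dc - np.einsum("xyk,xykt->xyt", coef, Gc)
    if n_constant:
        warnings.warn(
            f"{n_constant} constant stacked-partner series dropped from leakage designs",
            stacklevel=2,
        )
    # restore original axis order
    axes = [a for a in range(3) if a != run.slice_axis]
    if axes.index(omap.phase_axis) == 0:
        out = out.swapaxes(0, 1)
    out = np.moveaxis(out, 2, run.slice_axis)
    return run.with_data(out)


def shiftwise_correlations(
    run: BoldRun,
    part: SliceSetPartition,
    phase_axis: int = 1,
    max_voxels_per_slice: int = 4096,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean voxel-pair correlation between simultaneous slices versus phase shift.

    For every candidate shift delta (0 .. N_pe - 1) and every ordered
    within-set slice pair (earlier position u, later position v), the
    Pearson correlation between voxel (x, (y + delta) mod N_pe) of u and
    voxel (x, y) of v is computed, Fisher z-averaged over all pairs, and
    transformed back to r. Zero-variance voxels are excluded. For in-plane
    grids larger than ``max_voxels_per_slice`` a seeded random subsample of
    in-plane rows is used (recorded in the returned frame's attrs).

    Returns a DataFrame with columns (shift, mean_r, n_pairs).
    """
    if run.n_volumes < 3:
        raise ValueError("need at least 3 timepoints")
    vol, _ = _canonical(run, phase_axis)
    na, npe, ns, T = vol.shape
    sub_rows = None
    if na * npe > max_voxels_per_slice:
        rng = np.random.default_rng(seed)
        keep = max(1, max_voxels_per_slice // npe)
        sub_rows = np.sort(rng.choice(na, size=min(keep, na), replace=False))
        vol = vol[sub_rows]
        na = vol.shape[0]
    mean = vol.mean(axis=3, keepdims=True)
    sd = vol.std(axis=3, ddof=1, keepdims=True)
    valid = sd[..., 0] > 0
    Z = np.where(sd > 0, (vol - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    Z[~valid] = 0.0

    pairs = []
    for s in part.sets:
        for a in range(len(s)):
            for b in range(a + 1, len(s)):
                pairs.append((s[a] - 1, s[b] - 1))

    z_sum = np.zeros(npe)
    n_used = np.zeros(npe, dtype=np.int64)
    for u, v in pairs:
        Zv = Z[:, :, v, :]
        Vv = valid[:, :, v]
        for delta in range(npe):
            Zu = np.roll(Z[:, :, u, :], -delta, axis=1)
            Vu = np.roll(valid[:, :, u], -delta, axis=1)
            ok = Vu & Vv
            if not ok.any():
                continue
            r = np.einsum("xyt,xyt->xy", Zu, Zv) / (T - 1)
            r = r[ok]
            r = r[np.abs(r) < 1.0 - 1e-12]
            z_sum[delta] += np.arctanh(r).sum()
            n_used[delta] += r.size
    mean_r = np.where(n_used > 0, np.tanh(z_sum / np.maximum(n_used, 1)), np.nan)
    df = pd.DataFrame({"shift": np.arange(npe), "mean_r": mean_r, "n_pairs": n_used})
    df.attrs["subsample_seed"] = seed if sub_rows is not None else None
    return df
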