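"""Domain types and I/O for multiband BOLD runs.

This module owns the basic containers of the package: a 4D BOLD run with
its slice geometry, volume-wise rigid-body motion parameters, the standard
24-column motion nuisance expansion, and the partition of slices into
simultaneous-acquisition sets with their adjacent-to-simultaneous
comparison sets.

All slice indices exposed by these types are 1-based, matching the
convention of slice-correlation matrices in the QC literature; array
storage is 0-based internally.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "BoldRun",
    "MotionParams",
    "NuisanceMatrix",
    "SliceSetPartition",
    "load_bold",
    "save_bold",
    "load_motion",
    "expand_motion",
    "slice_partition",
]


@dataclass
class BoldRun:
    """A 4D BOLD fMRI run with its slice geometry.

    Parameters
    ----------
    data : ndarray
        4D array; the first three axes are spatial, the last is time.
    slice_axis : int
        Which spatial axis (0, 1 or 2) is the slice direction.
    tr_s : float
        Repetition time in seconds.
    slice_thickness_mm : float
        Slice spacing along ``slice_axis`` in millimetres.
    affine : ndarray, optional
        4x4 voxel-to-world affine, preserved on save.
    source_path : str
        Provenance string (file of origin, or a synthetic tag).
    """

    data: np.ndarray
    slice_axis: int = 2
    tr_s: float = 1.0
    slice_thickness_mm: float = 1.0
    affine: np.ndarray | None = None
    source_path: str = ""
    #: set False only for arrays produced by finite arithmetic on validated data
    check_finite: bool = True

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float64)
        if self.data.ndim != 4:
            raise ValueError(
                f"BoldRun requires a 4D (x, y, slice, time) array, got ndim={self.data.ndim}"
            )
        if self.slice_axis not in (0, 1, 2):
            raise ValueError("slice_axis must identify one spatial axis (0, 1 or 2)")
        if self.n_volumes < 2:
            raise ValueError("a timeseries needs at least 2 volumes")
        if self.n_slices < 2:
            raise ValueError("a run needs at least 2 slices")
        if self.check_finite and not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD intensities must be finite")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def n_slices(self) -> int:
        return self.data.shape[self.slice_axis]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def slices_last(self) -> np.ndarray:
        """View of the data with axes ordered (inplane, inplane, slice, time)."""
        return np.moveaxis(self.data, self.slice_axis, 2)

    def slice_data(self, j: int) -> np.ndarray:
        """Voxel timeseries of 1-based slice ``j`` as an (n_voxels, T) array."""
        if not 1 <= j <= self.n_slices:
            raise ValueError(f"slice index {j} outside 1..{self.n_slices}")
        sl = self.slices_last()[:, :, j - 1, :]
        return sl.reshape(-1, self.n_volumes)

    def with_data(
        self,
        data: np.ndarray,
        source_path: str | None = None,
        check_finite: bool = False,
    ) -> "BoldRun":
        """A copy of this run carrying new voxel data and the same geometry.

        Finiteness is not re-checked by default: the method exists for
        derived arrays (residuals, injected components) computed by finite
        arithmetic on already-validated data.
        """
        return BoldRun(
            data=data,
            slice_axis=self.slice_axis,
            tr_s=self.tr_s,
            slice_thickness_mm=self.slice_thickness_mm,
            affine=None if self.affine is None else self.affine.copy(),
            source_path=self.source_path if source_path is None else source_path,
            check_finite=check_finite,
        )


@dataclass
class MotionParams:
    """Volume-wise rigid-body head motion: T x 6 (mm, mm, mm, rad, rad, rad)."""

    params: np.ndarray
    dialect: str = "spm6"

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=np.float64)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion parameters must form a T x 6 matrix")
        if not np.all(np.isfinite(self.params)):
            raise ValueError("motion parameters must be finite")

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]


_EXPANSION_LABELS = (
    [f"{p}" for p in ("tx", "ty", "tz", "rx", "ry", "rz")]
    + [f"{p}^2" for p in ("tx", "ty", "tz", "rx", "ry", "rz")]
    + [f"d{p}" for p in ("tx", "ty", "tz", "rx", "ry", "rz")]
    + [f"d{p}^2" for p in ("tx", "ty", "tz", "rx", "ry", "rz")]
)


@dataclass
class NuisanceMatrix:
    """24-column motion nuisance matrix: params, squares, derivatives, squared derivatives.

    The intercept is *not* a column; design matrices add it separately.
    """

    M: np.ndarray
    column_labels: list[str] = field(default_factory=lambda: list(_EXPANSION_LABELS))

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=np.float64)
        if self.M.ndim != 2 or self.M.shape[1] != 24:
            raise ValueError("nuisance matrix must have exactly 24 columns")
        if not np.all(np.isfinite(self.M)):
            raise ValueError("nuisance matrix must be finite")

    @property
    def n_volumes(self) -> int:
        return self.M.shape[0]


@dataclass
class SliceSetPartition:
    """Partition of Ns slices into simultaneous-acquisition sets.

    With Ns slices and multiband factor MBf, there are NMB = Ns / MBf
    excitations per volume; the slices of one excitation are spaced NMB
    apart (interleaved multiband convention). ``simultaneous_of[j]`` is the
    set U_j (including j itself); ``adjacent_of[j]`` is the
    adjacent-to-simultaneous set: slices immediately above/below each
    member of U_j, clipped to the volume and excluding U_j itself.
    """

    mb_factor: int
    n_slices: int
    n_sets: int
    sets: list[tuple[int, ...]]
    simultaneous_of: dict[int, tuple[int, ...]]
    adjacent_of: dict[int, tuple[int, ...]]


def slice_partition(n_slices: int, mb_factor: int) -> SliceSetPartition:
    """Group ``n_slices`` into simultaneous slice sets for a given multiband factor.

    Raises if ``n_slices`` is not an exact multiple of ``mb_factor`` (the
    set construction presumes exact division) or if ``mb_factor < 2``
    (with a single slice per excitation there is no shared-slice artifact
    to speak of, and the estimator is ill-posed).
    """
    n_slices = int(n_slices)
    mb_factor = int(mb_factor)
    if mb_factor < 2:
        raise ValueError("multiband factor must be >= 2: no simultaneous slices otherwise")
    if n_slices % mb_factor != 0:
        raise ValueError(
            f"number of slices ({n_slices}) is not divisible by the multiband factor "
            f"({mb_factor}); every excitation must carry exactly MBf slices"
        )
    n_sets = n_slices // mb_factor
    sets = [
        tuple(range(r + 1, n_slices + 1, n_sets))
        for r in range(n_sets)
    ]
    simultaneous_of: dict[int, tuple[int, ...]] = {}
    adjacent_of: dict[int, tuple[int, ...]] = {}
    for s in sets:
        members = set(s)
        adj = set()
        for x in s:
            for y in (x - 1, x + 1):
                if 1 <= y <= n_slices:
                    adj.add(y)
        adj -= members
        for j in s:
            simultaneous_of[j] = s
            adjacent_of[j] = tuple(sorted(adj))
    return SliceSetPartition(
        mb_factor=mb_factor,
        n_slices=n_slices,
        n_sets=n_sets,
        sets=sets,
        simultaneous_of=simultaneous_of,
        adjacent_of=adjacent_of,
    )


def load_bold(
    path: str | os.PathLike,
    slice_axis: int = 2,
    tr_s: float | None = None,
    slice_thickness_mm: float | None = None,
) -> BoldRun:
    """Load a 4D NIFTI-1/2 BOLD run.

    TR and slice thickness are read from the header (pixdim) when present
    and can be overridden by the keyword arguments.
    """
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"{path}: not a 4D timeseries (ndim={img.ndim})")
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.shape[3] < 2:
        raise ValueError(f"{path}: fewer than 2 volumes")
    zooms = img.header.get_zooms()
    if tr_s is None:
        tr_s = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    if slice_thickness_mm is None:
        z = float(zooms[slice_axis])
        slice_thickness_mm = z if z > 0 else 1.0
    return BoldRun(
        data=data,
        slice_axis=slice_axis,
        tr_s=float(tr_s),
        slice_thickness_mm=float(slice_thickness_mm),
        affine=np.asarray(img.affine, dtype=np.float64),
        source_path=str(path),
    )


def save_bold(run: BoldRun, path: str | os.PathLike) -> None:
    """Write a run as a float32 NIFTI with scaling slope/intercept reset.

    Corrected data are residual-adjusted and can be negative, so the
    integer dtype of an input file is never preserved.
    """
    affine = run.affine if run.affine is not None else np.eye(4)
    img = nib.Nifti1Image(run.data.astype(np.float32), affine)
    zooms = [1.0, 1.0, 1.0]
    zooms[run.slice_axis] = run.slice_thickness_mm
    img.header.set_zooms((*zooms, run.tr_s))
    img.header["scl_slope"] = 1.0
    img.header["scl_inter"] = 0.0
    nib.save(img, str(path))


def load_motion(path: str | os.PathLike, dialect: str = "spm6") -> MotionParams:
    """Load volume-wise motion parameters from whitespace-delimited text.

    ``spm6``: 6 columns, translations in mm and rotations in radians
    (realignment ``rp_*.txt`` convention). ``hcp12``: >= 12 columns of
    which the first 6 are used; rotations are given in degrees and are
    converted to radians.
    """
    try:
        table = np.loadtxt(str(path), dtype=np.float64, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric token in motion file") from exc
    if dialect == "spm6":
        if table.shape[1] != 6:
            raise ValueError(
                f"{path}: spm6 motion files have 6 columns, found {table.shape[1]}"
            )
        params = table
    elif dialect == "hcp12":
        if table.shape[1] < 12:
            raise ValueError(
                f"{path}: hcp12 motion files have >= 12 columns, found {table.shape[1]}"
            )
        params = table[:, :6].copy()
        params[:, 3:6] = np.deg2rad(params[:, 3:6])
    else:
        raise ValueError(f"unknown motion dialect {dialect!r}")
    return MotionParams(params=params, dialect=dialect)


def expand_motion(mp: MotionParams) -> NuisanceMatrix:
    """Expand 6 rigid-body parameters to the standard 24-column nuisance set.

    Columns are ordered [p, p^2, dp, dp^2] where dp is the backward
    difference with a zero first row; squares of derivatives are taken
    after differencing.
    """
    p = mp.params
    dp = np.zeros_like(p)
    dp[1:] = np.diff(p, axis=0)
    M = np.hstack([p, p**2, dp, dp**2])
    return NuisanceMatrix(M=M)
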