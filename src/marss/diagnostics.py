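"""Quality-control diagnostics: tSNR, COV, temporal/spatial spectra, autocorrelation, BIC.

These are the measures used to characterize the isolated simultaneous-slice
artifact (approximately 1/f temporal spectrum, long-range autocorrelation)
and to quantify the benefit of removing it (temporal SNR up, coefficient of
variation down, spatial-frequency power of slice-profile maps down at the
simultaneous-slice spacing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .data import BoldRun, SliceSetPartition

__all__ = [
    "SpectrumReport",
    "tsnr_map",
    "mean_tsnr",
    "cov_map",
    "temporal_psd",
    "autocorrelation",
    "spatial_profile_psd",
    "bic",
    "qc_report",
]


@dataclass
class SpectrumReport:
    """A one-sided power spectrum with optional slope fit and spatial harmonics.

    ``freqs`` are Hz for temporal spectra and mm^-1 for spatial ones.
    ``fundamental`` is the spatial frequency of the simultaneous-slice
    spacing, 1 / (NMB * slice thickness); ``harmonics`` are its integer
    multiples up to the Nyquist frequency 1 / (2 * slice thickness).
    """

    freqs: np.ndarray
    psd: np.ndarray
    loglog_slope: float | None = None
    fundamental: float | None = None
    harmonics: np.ndarray | None = None
    degenerate: bool = False

    def power_at(self, freq: float) -> float:
        """Power at the frequency bin nearest ``freq``."""
        return float(self.psd[int(np.argmin(np.abs(self.freqs - freq)))])


def tsnr_map(run: BoldRun) -> np.ndarray:
    """Voxelwise temporal SNR: temporal mean over temporal SD (ddof=1).

    Voxels with zero temporal variance are undefined (NaN).
    """
    mean = run.data.mean(axis=3, dtype=np.float64)
    sd = run.data.std(axis=3, ddof=1, dtype=np.float64)
    out = np.full_like(mean, np.nan)
    ok = sd > 0
    out[ok] = mean[ok] / sd[ok]
    return out


def mean_tsnr(run: BoldRun, mask: np.ndarray | None = None) -> float:
    """Mean tSNR over a binary mask (whole volume if None); NaN voxels excluded."""
    t = tsnr_map(run)
    if mask is not None:
        mask = np.asarray(mask).astype(bool)
        if not mask.any():
            raise ValueError("empty mask")
        t = t[mask]
    return float(np.nanmean(t))


def cov_map(run: BoldRun, min_mean: float | None = None) -> np.ndarray:
    """Voxelwise temporal coefficient of variation: SD over mean.

    Voxels with |mean| below ``min_mean`` (default 1e-6 of the maximum
    absolute mean) are undefined (NaN).
    """
    mean = run.data.mean(axis=3, dtype=np.float64)
    sd = run.data.std(axis=3, ddof=1, dtype=np.float64)
    if min_mean is None:
        min_mean = 1e-6 * float(np.abs(mean).max())
    out = np.full_like(mean, np.nan)
    ok = np.abs(mean) > min_mean
    out[ok] = sd[ok] / mean[ok]
    return out


def temporal_psd(series: np.ndarray, tr_s: float, nperseg: int = 128) -> SpectrumReport:
    """Welch power spectral density of a timeseries, with a log-log slope fit.

    Hann window, 50% overlap, segment length min(T, nperseg), mean removal
    per segment. The slope is fitted on log10 power versus log10 frequency
    over all bins strictly above the lowest positive Welch frequency,
    characterising approximately power-law (1/f-like) signals.
    """
    x = np.asarray(series, dtype=np.float64)
    if x.ndim != 1 or x.size < 32:
        raise ValueError("temporal PSD needs a 1D series of at least 32 points")
    if np.var(x) == 0:
        return SpectrumReport(
            freqs=np.array([]), psd=np.array([]), degenerate=True
        )
    nper = min(x.size, nperseg)
    freqs, psd = signal.welch(
        x,
        fs=1.0 / tr_s,
        window="hann",
        nperseg=nper,
        noverlap=nper // 2,
        detrend="constant",
    )
    fit_mask = freqs > freqs[1] if freqs.size > 2 else np.zeros_like(freqs, bool)
    fit_mask &= psd > 0
    slope = None
    if fit_mask.sum() >= 2:
        coef = np.polyfit(np.log10(freqs[fit_mask]), np.log10(psd[fit_mask]), 1)
        slope = float(coef[0])
    return SpectrumReport(freqs=freqs, psd=psd, loglog_slope=slope)


def autocorrelation(series: np.ndarray, max_lag: int = 20) -> np.ndarray:
    """Biased sample autocorrelation at lags 0..max_lag, normalized to 1 at lag 0."""
    x = np.asarray(series, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("autocorrelation needs a 1D series with at least 2 points")
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0:
        raise ValueError("constant series has no autocorrelation")
    max_lag = min(max_lag, x.size - 1)
    acf = np.array([float(x[: x.size - k] @ x[k:]) / denom for k in range(max_lag + 1)])
    return acf


def spatial_profile_psd(
    map3d: np.ndarray,
    part: SliceSetPartition,
    slice_thickness_mm: float,
    slice_axis: int = 2,
) -> SpectrumReport:
    """Periodogram of the slice profile of a 3D map along the slice axis.

    The map is averaged over the two in-plane axes (one value per slice),
    mean-centered, and transformed with a plain (rectangular-window)
    periodogram sampled at 1 / slice thickness. A component that is
    constant within each simultaneous slice set but varies across sets is
    periodic with period NMB slices and concentrates power at the
    fundamental 1 / (NMB * thickness) and its harmonics.
    """
    m = np.moveaxis(np.asarray(map3d, dtype=np.float64), slice_axis, 2)
    if m.shape[2] != part.n_slices:
        raise ValueError("map slice count does not match the partition")
    profile = m.mean(axis=(0, 1))
    profile = profile - profile.mean()
    freqs, psd = signal.periodogram(
        profile,
        fs=1.0 / slice_thickness_mm,
        window="boxcar",
        detrend=False,
        scaling="spectrum",
    )
    fundamental = 1.0 / (part.n_sets * slice_thickness_mm)
    nyquist = 1.0 / (2.0 * slice_thickness_mm)
    harmonics = fundamental * np.arange(1, int(np.floor(nyquist / fundamental)) + 1)
    return SpectrumReport(
        freqs=freqs, psd=psd, fundamental=fundamental, harmonics=harmonics
    )


def bic(
    n_volumes: int,
    res_ms: float,
    dof_used: int,
    marss_corrected: bool = False,
    res_ms_times_n: bool = False,
) -> float:
    """Model-fit criterion penalized by degrees of freedom.

    ``BIC = N ln(2 pi) + N + N ln(resMS) - DOF ln(N)``, with the artifact
    correction flag decrementing DOF by one (the per-voxel regression
    spends one degree of freedom on the artifact direction). The
    ``res_ms_times_n`` switch replaces resMS with resMS * N inside the
    logarithm; it is off by default.
    """
    N = int(n_volumes)
    if res_ms <= 0:
        raise ValueError("mean squared residuals must be positive")
    if not N > dof_used >= 0:
        raise ValueError("require n_volumes > dof_used >= 0")
    dof = dof_used - 1 if marss_corrected else dof_used
    inner = res_ms * N if res_ms_times_n else res_ms
    return float(N * np.log(2 * np.pi) + N + N * np.log(inner) - dof * np.log(N))


def qc_report(
    run: BoldRun,
    part: SliceSetPartition,
    mask: np.ndarray | None = None,
    max_lag: int = 20,
) -> dict:
    """Aggregate per-run QC numbers into one JSON-serializable dict."""
    gs = run.data.reshape(-1, run.n_volumes).mean(axis=0, dtype=np.float64)
    out: dict = {
        "n_slices": run.n_slices,
        "n_volumes": run.n_volumes,
        "tr_s": run.tr_s,
        "mb_factor": part.mb_factor,
        "mean_tsnr": mean_tsnr(run, mask),
        "mean_cov": float(np.nanmean(cov_map(run)[mask] if mask is not None else cov_map(run))),
    }
    if run.n_volumes >= 32:
        sp = temporal_psd(gs, run.tr_s)
        out["global_psd_slope"] = sp.loglog_slope
    out["global_acf"] = autocorrelation(gs, max_lag).tolist()
    return out
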