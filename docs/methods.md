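# Methods

## The artifact and the detection statistic

Simultaneous multi-slice (multiband, SMS) EPI excites and reads out MBf
slices per RF shot. The slices of one shot — spaced NMB = Ns/MBf apart in
an interleaved acquisition — share a low-amplitude nuisance signal that is
essentially identical across the set up to a voxelwise gain. The package
detects it with a slice-pair correlation contrast: for every slice j, the
mean slice timeseries is computed, residualized on an intercept plus the
24-column motion expansion (the six rigid-body parameters, their squares,
backward differences, and squared differences; zero-padded first row), and
Pearson-correlated with every other slice. The statistic

    r_U-Y = tanh( mean_z{ r(j, k) : k simultaneous with j }
                − mean_z{ r(j, k) : k adjacent to the simultaneous set } )

averages Fisher-z-transformed correlations over all ordered pairs and
transforms the difference back to r. Adjacent-to-simultaneous slices are
the null comparison: they share anatomy and BOLD smoothness with the set
members, so under no artifact the contrast is ~0. Self-pairs are excluded
(their z diverges); zero-variance or |r| = 1 pairs are dropped with a
warning rather than imputed. Denominators are the number of terms actually
summed — the only reading under which the closed-form check
tanh(artanh 0.5 − artanh 0.2) = 1/3 holds.

## Estimation and removal

Estimation (per slice j): s_j is the mean timeseries over all voxels of
the slices simultaneous with j, excluding j itself; g_Uj is the mean over
all voxels of every *non*-simultaneous slice; the artifact estimate a_j is
the OLS residual of s_j on [1, g_Uj, M] (26 columns with motion). a_j is
by construction orthogonal to the intercept, the global signal proxy, and
motion.

Removal (per voxel i of slice j): the timeseries d_ij is regressed on
[1, a_j, g_Uj, M] and only the fitted a_j component (coefficient × a_j) is
subtracted. Exactly one degree of freedom is spent per voxel; the
corrected run plus the stored voxelwise artifact reconstructs the input
exactly (to float precision). All solves go through the SVD pseudoinverse
— identical to the normal equations at full rank, well-defined otherwise —
with a scale-invariant condition check (columns normalized to unit norm;
warn above 1e12) so that regressors on different physical scales (raw
intensity vs. mm vs. rad) do not trip false alarms.

The artifact magnitude map A is the temporal mean of |voxelwise artifact|,
optionally rescaled to percent of mean voxel intensity (voxels below an
intensity floor excluded).

Variants restrict which voxels feed s_j: `background_only` uses only
voxels outside the brain mask dilated by one voxel (6-connectivity). The
restriction applies to the artifact source average s_j; the global
regressor g_Uj remains all-voxel, since its role is to capture global
(largely brain) signal and masking the brain out of it would defeat that.
`thresholded` (top-p%) runs a standard pass, keeps the top p% of voxels
per slice by artifact magnitude, and re-estimates s_j as the binary-
weighted average over those voxels in the partner slices.

## Interslice leakage

CAIPI-shifted acquisitions overlay simultaneous slices after in-plane
shifts of round(N_pe/denominator) voxels (34 for a 102-voxel matrix with
an FOV/3 shift). The stacked partner of voxel (x, y) in a slice with
shift s, within a slice of shift s′, is (x, (y + s − s′) mod N_pe).
`leakage_regression` residualizes every voxel on its MBf−1 stacked
partners (deliberately destructive — a probe for whether shared-slice
structure survives leakage removal, not a denoiser), and
`shiftwise_correlations` reports the Fisher-averaged voxel-pair
correlation between simultaneous slices as a function of the in-plane
shift. The slice artifact lives in whole slices, not stacked voxel pairs:
removing one leaves the other's readout essentially unchanged, which the
acceptance checks quantify.

## Diagnostics

- tSNR: temporal mean / SD (ddof 1); COV its reciprocal. Removing a
  component that is orthogonal to the residual leaves voxel means intact
  and lowers SD, so tSNR rises wherever the fitted loading is nonzero.
- Temporal PSD: Welch, Hann window, segments of min(T, 128), 50% overlap,
  mean removal; log10–log10 slope fitted over all bins strictly above the
  lowest positive Welch frequency. The isolated artifact is approximately
  1/f with slopes near −0.8.
- Autocorrelation: biased sample ACF normalized at lag 0.
- Spatial-profile PSD: a 3D map is averaged in-plane to one value per
  slice, mean-centered, and transformed with a rectangular-window
  periodogram sampled at 1/slice-thickness ("spectrum" scaling, so the
  one-sided power sums to the profile variance — Parseval is asserted in
  tests). A component constant within each simultaneous set is periodic
  with period NMB slices and concentrates power at the fundamental
  1/(NMB·dz) and its harmonics; at Ns = 60, MB 6, dz = 2 mm the
  fundamental falls exactly on periodogram bin MBf.
- BIC: N·ln 2π + N + N·ln resMS − DOF·ln N, implemented exactly in this
  arrangement (no silent normalization to the textbook form); the
  artifact-correction flag decrements DOF by one. A switch selects the
  resMS·N reading of the penalized term; it is off by default.

## The synthetic generator

`SyntheticSpec` defines the study conditions; `generate(spec)` is fully
reproducible from the single mandatory seed. Components, in raw intensity
units against a brain baseline of 1000 and background 20 (ellipsoidal
"brain" in a 64×64×60 grid, 2 mm slices, MB 6 → 10 simultaneous sets,
640 volumes at TR 0.8 s ≈ an 8.5-minute run):

- Artifact: one unit-variance series per simultaneous set, synthesized
  with a power-law spectrum of exponent −0.8 (random phases), injected
  identically into every voxel of the set's slices scaled by an amplitude
  map — background 1×, brain 2×, vascular-like foci (2% of brain voxels)
  5× — times `artifact_amplitude` = 0.5. The tiers reproduce the
  qualitative spatial ordering seen in vivo (vasculature strongest,
  artifact present in the image background); the absolute values are a
  package choice.
- Global signal: a 1/f series × 0.25 in brain voxels.
- Slice-wise structured signal: an independent 1/f series per slice × 0.4
  in brain voxels — the stand-in for neural/physiological variance that
  correction must leave untouched. Without it, post-correction slice
  means would be pure noise and the adjacent-slice null comparison would
  be degenerate.
- Motion: realignment-like traces (white volume-to-volume jitter plus a
  15% smooth mean-reverting drift; translations jitter SD 0.03 mm,
  rotations a tenth of that), plus a motion-coupled brain component built
  from a standardized mixture of the six parameters.
- Unstructured noise: i.i.d. Gaussian, SD 10 — an order of magnitude above
  the per-voxel artifact, so detection and estimation must rely on slice
  averaging, as they do in vivo (brain tSNR ≈ 100).
- Optional leakage: each slice receives `leakage_amp` × the stacked-partner
  fluctuation of the previous within-set position at the configured CAIPI
  shift.

Amplitudes were calibrated once so the synthetic run sits in the regime
reported for real scanners — pre-correction r_U-Y far above 0.3, artifact
1/f exponent inside the measured slope range — and were then frozen.
Because the artifact's *fractional* share of slice-mean variance is larger
here than in vivo, the synthetic pre-correction statistic (~0.9) overshoots
the in vivo 0.3–0.4 range; the checks only require the artifact regime
(≥ 0.3).

What the generator does not emulate: anatomy beyond an ellipsoid, EPI
distortion, k-space/GRAPPA reconstruction, physiological waveforms, and
spatial autocorrelation of the noise. Passing tests therefore demonstrate
the estimator's behavior under the assumed forward model, not performance
on any particular scanner's data.

### Problem sizes and precision

Default-condition batches use 20 seeds at 64×64×60×640 (float32 storage,
~630 MB per run; regressions are solved per-slice in float64). The
exact-decomposition check runs on a 40×40×30×200 float64 run, where
original = corrected + artifact holds to < 1e−10 of the data scale; with
float32 storage the identity holds to float32 rounding (~1e−7).

### Two structural results worth knowing

Both are properties of the estimator, reproduced faithfully here.

1. *Run length and geometry bound recovery accuracy.* Any OLS on p
   regressors removes ≈ p/T of an independent component's sample variance
   by chance, so corr(â_j, true artifact) ≤ √(1 − 26/T); and the
   non-simultaneous global regressor carries a 1/√(NMB−1) mixture of the
   *other* sets' artifacts, bounding recovery near 1/√(1 + 1/(NMB−1)).
   Accurate recovery (≥ 0.95) therefore needs both a long run and many
   simultaneous sets — the regime of real 2 mm MB6 protocols, and of the
   generator defaults.

2. *Accurate removal slightly overcorrects the statistic.* Because a_j is
   a leave-one-out partner average, each slice's independent variance
   appears (divided by MBf−1) in its partners' artifact estimates; fitting
   and removing it induces a negative correlation among corrected
   simultaneous slices with a Fisher-averaged floor near −0.1 for MBf = 6.
   The post-correction statistic on default synthetic data is ≈ −0.13,
   the direct analogue of the small negative difference standard
   correction induces on real data; the thresholded variants trade a
   little estimation SNR for less overcorrection, and the package
   reproduces that ordering.

## Known limitations

- Rigid-body motion must be supplied externally (realignment is out of
  scope); without it the nuisance block is empty and artifact estimates
  absorb motion-coupled signal.
- The method presumes the interleaved simultaneous-slice convention
  (members of a set spaced NMB apart); acquisitions with other orderings
  need an explicit partition.
- The leakage analysis models the stacked-voxel geometry only; it is not a
  reconstruction-level (split-slice-GRAPPA) model.
- Statistics are per-run; multi-run aggregation is limited to the paired
  signed-rank comparison of per-run statistics.
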