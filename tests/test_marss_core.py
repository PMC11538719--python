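"""Artifact estimation, voxelwise removal, magnitude maps, and variants."""

import numpy as np
import pytest

import marss
from marss.data import expand_motion, slice_partition
from marss.model import (
    ArtifactEstimate,
    estimate_artifact,
    magnitude_map,
    nonsimultaneous_global,
    remove_artifact,
    simultaneous_mean,
)

from conftest import make_run, ols_oracle


class TestSimultaneousMean:
    def test_constant_image(self):
        run = marss.BoldRun(data=np.full((4, 4, 6, 8), 3.0))
        part = slice_partition(6, 3)
        np.testing.assert_allclose(simultaneous_mean(run, part, 1), 3.0)

    def test_uniform_weights_match_unweighted(self, rng):
        run = make_run(rng, shape=(5, 5, 6, 10))
        part = slice_partition(6, 2)
        w = np.full(run.spatial_shape, 0.7)
        np.testing.assert_allclose(
            simultaneous_mean(run, part, 2, weights=w),
            simultaneous_mean(run, part, 2),
            rtol=1e-12,
        )

    def test_triple_loop_oracle(self, rng):
        run = make_run(rng, shape=(4, 5, 6, 7))
        part = slice_partition(6, 3)
        for j in (1, 4):
            partners = [u for u in part.simultaneous_of[j] if u != j]
            expect = np.zeros(7)
            for t in range(7):
                vals = [run.data[x, y, u - 1, t]
                        for u in partners
                        for x in range(4) for y in range(5)]
                expect[t] = np.mean(vals)
            np.testing.assert_allclose(simultaneous_mean(run, part, j), expect,
                                       atol=1e-12)

    def test_empty_weights_error(self, rng):
        run = make_run(rng, shape=(4, 4, 6, 8))
        part = slice_partition(6, 3)
        with pytest.raises(ValueError, match="contributing"):
            simultaneous_mean(run, part, 1, weights=np.zeros(run.spatial_shape))


class TestNonsimultaneousGlobal:
    def test_constant_image(self):
        run = marss.BoldRun(data=np.full((3, 3, 6, 5), 9.0))
        part = slice_partition(6, 2)
        np.testing.assert_allclose(nonsimultaneous_global(run, part, 1), 9.0)

    def test_identical_within_set(self, rng):
        run = make_run(rng, shape=(4, 4, 8, 6))
        part = slice_partition(8, 2)
        g1 = nonsimultaneous_global(run, part, 1)
        g5 = nonsimultaneous_global(run, part, 5)  # same set as slice 1
        np.testing.assert_array_equal(g1, g5)

    def test_loop_oracle(self, rng):
        run = make_run(rng, shape=(3, 4, 6, 5))
        part = slice_partition(6, 3)
        others = [u for u in range(1, 7) if u not in part.simultaneous_of[2]]
        expect = np.mean(
            [run.data[:, :, u - 1, :] for u in others], axis=(0, 1, 2)
        )
        np.testing.assert_allclose(nonsimultaneous_global(run, part, 2), expect,
                                   atol=1e-12)

    def test_all_simultaneous_error(self, rng):
        run = make_run(rng, shape=(3, 3, 4, 6))
        part = slice_partition(4, 4)
        with pytest.raises(ValueError, match="non-simultaneous"):
            nonsimultaneous_global(run, part, 1)


class TestEstimateArtifact:
    def test_design_span_gives_zero_artifact(self, rng):
        # every voxel follows the same global series -> s_j in span([1, g])
        series = rng.normal(size=20)
        data = np.empty((4, 4, 6, 20))
        data[...] = 50.0 + 3.0 * series
        run = marss.BoldRun(data=data)
        part = slice_partition(6, 3)
        est = estimate_artifact(run, part)
        assert np.abs(est.a).max() < 1e-8

    def test_residual_orthogonal_to_design(self, rng):
        run = make_run(rng, shape=(5, 5, 8, 30))
        part = slice_partition(8, 4)
        nuis = expand_motion(marss.MotionParams(rng.normal(size=(30, 6))))
        est = estimate_artifact(run, part, nuis)
        for j in (1, 5):
            design = np.column_stack([np.ones(30), est.g[j - 1], nuis.M])
            proj = design.T @ est.a[j - 1]
            assert np.abs(proj).max() < 1e-8 * np.linalg.norm(est.a[j - 1]) * 30

    def test_normal_equations_oracle(self, rng):
        # zero baseline keeps the Gram-matrix oracle itself well conditioned
        run = make_run(rng, shape=(4, 4, 6, 60), base=0.0)
        part = slice_partition(6, 2)
        nuis = expand_motion(marss.MotionParams(0.1 * rng.normal(size=(60, 6))))
        est = estimate_artifact(run, part, nuis)
        for j in (1, 3, 6):
            s_j = simultaneous_mean(run, part, j)
            g_j = nonsimultaneous_global(run, part, j)
            design = np.column_stack([np.ones(60), g_j, nuis.M])
            _, resid = ols_oracle(design, s_j)
            np.testing.assert_allclose(est.a[j - 1], resid, atol=1e-8)


class TestRemoveArtifact:
    @staticmethod
    def _fit_small(rng):
        run = make_run(rng, shape=(4, 4, 6, 40))
        part = slice_partition(6, 3)
        nuis = expand_motion(marss.MotionParams(0.1 * rng.normal(size=(40, 6))))
        est = estimate_artifact(run, part, nuis)
        return run, part, nuis, est

    def test_pure_loading_recovered_exactly(self, rng):
        run, part, nuis, est = self._fit_small(rng)
        # build a run whose every voxel is 3*a_j + 7: the fitted artifact
        # component must be exactly 3*a_j and the corrected data constant
        data = np.empty_like(run.data)
        for j in range(6):
            data[:, :, j, :] = 7.0 + 3.0 * est.a[j]
        run2 = marss.BoldRun(data=data)
        corrected, est2 = remove_artifact(run2, est, part, nuis)
        for j in range(6):
            np.testing.assert_allclose(
                est2.artifact_4d[:, :, j, :],
                np.broadcast_to(3.0 * est.a[j], (4, 4, 40)),
                atol=1e-8,
            )
        assert np.abs(corrected.data - 7.0).max() < 1e-8

    def test_exact_decomposition(self, rng):
        run, part, nuis, est = self._fit_small(rng)
        corrected, est = remove_artifact(run, est, part, nuis)
        err = np.abs(run.data - (corrected.data + est.artifact_4d)).max()
        assert err <= 1e-10 * np.abs(run.data).max()

    def test_artifact_direction_fully_projected(self, rng):
        # regressing corrected voxels on the removal design returns ~0 on a_j
        run, part, nuis, est = self._fit_small(rng)
        corrected, est = remove_artifact(run, est, part, nuis)
        for j in (1, 4):
            design = np.column_stack(
                [np.ones(40), est.a[j - 1], est.g[j - 1], nuis.M]
            )
            coefs, _ = ols_oracle(design, corrected.slice_data(j).T)
            assert np.abs(coefs[1]).max() < 1e-8

    def test_voxel_regression_matches_oracle(self, rng):
        run, part, nuis, est = self._fit_small(rng)
        corrected, est = remove_artifact(run, est, part, nuis)
        j = 2
        design = np.column_stack([np.ones(40), est.a[j - 1], est.g[j - 1], nuis.M])
        coefs, _ = ols_oracle(design, run.slice_data(j).T)
        got = est.beta_maps[:, :, j - 1].ravel()
        np.testing.assert_allclose(got, coefs[1], atol=1e-8)


class TestMagnitudeMap:
    def test_alternating_sign(self):
        art = np.ones((2, 2, 2, 10)) * 0.4
        art[..., ::2] *= -1
        est = ArtifactEstimate(a=np.zeros((2, 10)), g=np.zeros((2, 10)))
        est.artifact_4d = art
        np.testing.assert_allclose(magnitude_map(est), 0.4)

    def test_zero_artifact(self):
        est = ArtifactEstimate(a=np.zeros((2, 6)), g=np.zeros((2, 6)))
        est.artifact_4d = np.zeros((3, 3, 2, 6))
        np.testing.assert_allclose(magnitude_map(est), 0.0)

    def test_elementwise_oracle(self, rng):
        art = rng.normal(size=(3, 3, 4, 12))
        est = ArtifactEstimate(a=np.zeros((4, 12)), g=np.zeros((4, 12)))
        est.artifact_4d = art
        np.testing.assert_allclose(
            magnitude_map(est), np.abs(art).mean(axis=3), atol=1e-12
        )

    def test_not_computed_error(self):
        est = ArtifactEstimate(a=np.zeros((2, 6)), g=np.zeros((2, 6)))
        with pytest.raises(ValueError, match="not computed"):
            magnitude_map(est)


class TestNullInertness:
    def test_small_null_run_nearly_untouched(self):
        spec = marss.SyntheticSpec(
            nx=16, ny=16, n_slices=12, n_volumes=160, mb_factor=4,
            artifact_amplitude=0.0, dtype="float64", seed=7,
        )
        ds = marss.generate(spec)
        res = marss.run_marss(ds.run, 4, motion=ds.motion)
        var_art = np.var(res.estimate.artifact_4d, axis=3)
        var_tot = np.var(ds.run.data, axis=3)
        frac = var_art / var_tot
        assert np.median(frac) <= 0.02


@pytest.fixture(scope="module")
def medium_fits():
    spec = marss.SyntheticSpec(nx=48, ny=48, n_volumes=320, seed=21)
    ds = marss.generate(spec)
    std = marss.run_marss(ds.run, 6, motion=ds.motion)
    bg = marss.run_marss(
        ds.run, 6, motion=ds.motion, variant="background_only",
        brain_mask=ds.brain_mask,
    )
    thr = marss.run_marss(
        ds.run, 6, motion=ds.motion, variant="thresholded",
        threshold_percent=30,
    )
    return ds, std, bg, thr


class TestVariants:
    def test_background_only_partial_reduction(self, medium_fits):
        ds, std, bg, _ = medium_fits
        pre = std.report_pre.r_U_minus_Y
        # background-only estimation reduces the statistic, but by less
        # than the standard variant
        assert bg.report_post.r_U_minus_Y < pre
        assert pre - bg.report_post.r_U_minus_Y < pre - std.report_post.r_U_minus_Y

    def test_thresholded_close_to_standard(self, medium_fits):
        # the thresholded variant removes the artifact as completely as the
        # standard one; it differs mainly in inducing less overcorrection
        # (a smaller negative post-correction statistic)
        _, std, _, thr = medium_fits
        red_std = std.report_pre.r_U_minus_Y - std.report_post.r_U_minus_Y
        red_thr = thr.report_pre.r_U_minus_Y - thr.report_post.r_U_minus_Y
        assert abs(red_std - red_thr) < 0.1
        assert thr.report_post.r_U_minus_Y < 0.1
        assert abs(thr.report_post.r_U_minus_Y) <= abs(std.report_post.r_U_minus_Y) + 0.05

    def test_thresholded_weights_per_slice(self, medium_fits):
        _, _, _, thr = medium_fits
        w = thr.estimate.weights
        assert w is not None
        per_slice = w.sum(axis=(0, 1)) / (48 * 48)
        # top 30% per slice, up to percentile ties
        np.testing.assert_allclose(per_slice, 0.30, atol=0.02)

    def test_variant_validation(self, small_ds):
        with pytest.raises(ValueError, match="variant"):
            marss.MARSS(small_ds.run, 4, variant="bogus")
        with pytest.raises(ValueError, match="mask"):
            marss.MARSS(small_ds.run, 4, variant="background_only")
        with pytest.raises(ValueError, match="threshold"):
            marss.MARSS(small_ds.run, 4, variant="thresholded")
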