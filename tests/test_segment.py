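"""Coupled level-set segmentation: initialization, local statistics,
thickness estimation and constrained evolution."""

import numpy as np
import pytest
from scipy import ndimage

from longbrain.grid import ImageGrid
from longbrain.levelset import (CSF, GM, WM, LevelSetState, SegWeights,
                                _signed_distance, estimate_thickness,
                                evolve_segmentation, fit_local_stats,
                                init_levelsets, register_tissue_maps,
                                segment_series_4d)


def _strip(series, truth):
    return [s.like(np.where(truth.brain_masks[t], s.voxels, 0.0)
                   .astype(np.float32)) for t, s in enumerate(series)]


def _shell_state(r_wm=14.0, r_gm=17.0, r_brain=20.0, n=48):
    """Analytic concentric-sphere state built from voxelized regions."""
    origin = -np.full(3, (n - 1) / 2.0)
    ii, jj, kk = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
    r = np.sqrt((ii + origin[0]) ** 2 + (jj + origin[1]) ** 2
                + (kk + origin[2]) ** 2)
    geom = ImageGrid(np.zeros((n, n, n)), origin=origin)
    sp = geom.spacing
    return LevelSetState(_signed_distance(r < r_wm, sp),
                         _signed_distance(r < r_gm, sp),
                         _signed_distance(r < r_brain, sp), geom), r


class TestInit:
    def test_noiseless_phantom_with_exact_priors_recovers_truth(
            self, clean_phantom):
        series, truth, atlas = clean_phantom
        brain = _strip(series, truth)[0]
        state = init_levelsets(brain, atlas.tissue_priors)
        agree = (state.labels() == truth.tissue_labels[0]).mean()
        assert agree > 0.999

    def test_truth_wm_has_negative_phi(self, clean_phantom):
        series, truth, atlas = clean_phantom
        brain = _strip(series, truth)[0]
        state = init_levelsets(brain, atlas.tissue_priors)
        wm = truth.tissue_labels[0] == WM
        # interior WM voxels (eroded by one voxel) are strictly inside
        wm_core = ndimage.binary_erosion(wm)
        assert (state.phi_wm[wm_core] < 0).all()

    def test_flat_priors_reduce_to_global_em(self, clean_phantom):
        series, truth, atlas = clean_phantom
        brain = _strip(series, truth)[0]
        flat = {k: v.like(np.full(v.shape, 1 / 3, dtype=np.float32))
                for k, v in atlas.tissue_priors.items()}
        state = init_levelsets(brain, flat)
        # separable classes: EM thresholding alone recovers the anatomy
        agree = (state.labels() == truth.tissue_labels[0]).mean()
        assert agree > 0.999

    def test_nesting_holds(self, small_phantom):
        series, truth, atlas = small_phantom
        brain = _strip(series, truth)[0]
        state = init_levelsets(brain, atlas.tissue_priors)
        assert state.nesting_ok()


class TestLocalStats:
    def test_constant_region_mean_and_floor_variance(self, clean_phantom):
        series, truth, atlas = clean_phantom
        brain = _strip(series, truth)[0]
        state = init_levelsets(brain, atlas.tissue_priors)
        stats = fit_local_stats(brain, state, window_fwhm=10.0)
        wm_core = ndimage.binary_erosion(truth.tissue_labels[0] == WM,
                                         iterations=3)
        np.testing.assert_allclose(stats.mean["wm"][wm_core], 120.0,
                                   atol=1.0)
        assert (stats.variance["wm"][wm_core]
                <= 1.0 + 1e-6).all()  # at the regularization floor

    def test_two_half_volume_local_means(self):
        n = 40
        vox = np.full((n, n, n), 100.0)
        vox[n // 2:] = 120.0
        geom = ImageGrid(vox, origin=(-(n - 1) / 2.0,) * 3)
        state = LevelSetState(
            np.full((n, n, n), -10.0, dtype=np.float32),   # all WM
            np.full((n, n, n), -12.0, dtype=np.float32),
            np.full((n, n, n), -14.0, dtype=np.float32), geom)
        stats = fit_local_stats(geom, state, window_fwhm=6.0)
        m = stats.mean["wm"]
        assert abs(m[5, n // 2, n // 2] - 100.0) < 0.5
        assert abs(m[n - 5, n // 2, n // 2] - 120.0) < 0.5
        # transition confined to the boundary region
        assert 100.0 < m[n // 2, n // 2, n // 2] < 120.0

    def test_infinite_window_equals_global_mean(self, clean_phantom):
        series, truth, atlas = clean_phantom
        brain = _strip(series, truth)[0]
        state = init_levelsets(brain, atlas.tissue_priors)
        stats = fit_local_stats(brain, state, window_fwhm=1e4)
        lab = state.labels()
        g = brain.voxels[lab == GM].mean()
        sel = lab == GM
        np.testing.assert_allclose(stats.mean["gm"][sel], g, atol=1e-3)


class TestThickness:
    def test_concentric_shell_analytic_distances_exact(self):
        """With exact signed radial distances the summed-distance thickness
        of a 30/33 mm shell is exactly 3 mm at every GM voxel."""
        n = 72
        origin = -np.full(3, (n - 1) / 2.0)
        ii, jj, kk = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
        r = np.sqrt((ii + origin[0]) ** 2 + (jj + origin[1]) ** 2
                    + (kk + origin[2]) ** 2)
        geom = ImageGrid(np.zeros((n, n, n)), origin=origin)
        state = LevelSetState((r - 30.0).astype(np.float32),
                              (r - 33.0).astype(np.float32),
                              (r - 35.0).astype(np.float32), geom)
        tm = estimate_thickness(state)
        np.testing.assert_allclose(tm.thickness[tm.gm_mask], 3.0, atol=1e-3)

    def test_concentric_shell_from_voxelized_regions(self):
        """The same shell built from voxelized regions (EDT-based signed
        distances) measures 3 mm within the discretization tolerance."""
        state, r = _shell_state(r_wm=30.0, r_gm=33.0, r_brain=35.0, n=72)
        tm = estimate_thickness(state)
        assert abs(tm.thickness[tm.gm_mask].mean() - 3.0) < 0.2

    def test_thin_limit(self):
        state, _ = _shell_state(r_wm=14.0, r_gm=15.0)
        tm = estimate_thickness(state)
        assert abs(tm.thickness[tm.gm_mask].mean() - 1.0) < 0.35

    def test_rotation_invariance(self):
        state, _ = _shell_state()
        tm = estimate_thickness(state)
        rot = LevelSetState(
            ndimage.rotate(state.phi_wm, 30, axes=(0, 1), reshape=False,
                           order=1, mode="nearest"),
            ndimage.rotate(state.phi_gm, 30, axes=(0, 1), reshape=False,
                           order=1, mode="nearest"),
            ndimage.rotate(state.phi_csf, 30, axes=(0, 1), reshape=False,
                           order=1, mode="nearest"), state.geometry)
        tm_rot = estimate_thickness(rot)
        assert abs(tm_rot.mean() - tm.mean()) < 0.2


class TestEvolution:
    def test_thin_gap_repaired_to_constraint_band(self):
        """A artificially thin (sub-voxel) GM gap must be pushed back above
        the 1 mm lower bound by the spatial thickness constraint."""
        n = 48
        state, r = _shell_state(r_wm=16.6, r_gm=17.0, n=n)
        vox = np.where(r < 16.6, 120.0, np.where(r < 17.0, 80.0,
                       np.where(r < 20.0, 40.0, 0.0)))
        geom = ImageGrid(vox.astype(np.float32), origin=state.geometry.origin)
        state.geometry = geom
        stats = fit_local_stats(geom, state, window_fwhm=10.0)
        w = SegWeights(lambda_data=0.2, lambda_spatial_thick=1.0, iters=60)
        out = evolve_segmentation(geom, state, stats, None, w)
        tm = estimate_thickness(out)
        assert tm.thickness[tm.gm_mask].mean() >= 1.0

    def test_equal_neighbor_thickness_gives_zero_temporal_update(self):
        state, _ = _shell_state()
        n = state.phi_wm.shape[0]
        vox = np.where(state.phi_csf < 0, 80.0, 0.0)
        geom = ImageGrid(vox.astype(np.float32),
                         origin=state.geometry.origin)
        state.geometry = geom
        stats = fit_local_stats(geom, state, window_fwhm=10.0)
        tm = estimate_thickness(state)
        w = SegWeights(lambda_data=0.0, lambda_spatial_thick=0.0,
                       mu_smooth=0.0, iters=5, reinit_every=100)
        with_nb = evolve_segmentation(geom, state, stats, (tm, tm), w)
        without = evolve_segmentation(geom, state, stats, None, w)
        np.testing.assert_allclose(with_nb.phi_wm, without.phi_wm,
                                   atol=1e-5)

    def test_nesting_and_partition_after_evolution(self, small_phantom):
        series, truth, atlas = small_phantom
        brains = _strip(series, truth)
        labels, _ = segment_series_4d(brains[:1], atlas.tissue_priors,
                                      SegWeights(iters=30))
        assert set(np.unique(labels[0].voxels)) <= {0, 1, 2, 3}
        assert ((labels[0].voxels > 0) == truth.brain_masks[0]).all()

    def test_single_timepoint_matches_explicit_3d_path(self, small_phantom):
        series, truth, atlas = small_phantom
        brains = _strip(series, truth)
        w = SegWeights(iters=30)
        labels_series, _ = segment_series_4d(brains[:1],
                                             atlas.tissue_priors, w)
        from longbrain.levelset import (evolve_segmentation,
                                        fit_local_stats, init_levelsets)
        st = init_levelsets(brains[0], atlas.tissue_priors)
        stats = fit_local_stats(brains[0], st, 15.0)
        st = evolve_segmentation(brains[0], st, stats, None, w)
        np.testing.assert_array_equal(labels_series[0].voxels, st.labels())


class TestTissueMapRegistration:
    def test_identical_segmentations_give_near_zero_field(self,
                                                          small_phantom):
        series, truth, atlas = small_phantom
        lab = truth.tissue_labels[0]
        d = register_tissue_maps(lab, lab, series[0])
        assert np.linalg.norm(d, axis=-1).mean() < 0.1

    @staticmethod
    def _blob_labels(n=48):
        """Asymmetric nested blob (translation is unambiguous, unlike a
        centred sphere)."""
        lab = np.zeros((n, n, n), dtype=np.uint8)
        lab[18:32, 16:34, 14:30] = 2
        lab[22:28, 20:30, 18:26] = 3
        geom = ImageGrid(np.zeros((n, n, n)), origin=(-(n - 1) / 2.0,) * 3)
        return lab, geom

    def test_translation_recovered(self):
        lab, geom = self._blob_labels()
        shifted = np.roll(lab, 3, axis=0)
        d = register_tissue_maps(lab, shifted, geom)
        inside = ndimage.binary_erosion(lab > 0, iterations=2)
        # shifted(x + d) == lab(x) requires a sampling offset of +3 along x
        assert abs(d[inside][:, 0].mean() - 3.0) < 0.5
        assert np.abs(d[inside][:, 1:].mean(axis=0)).max() < 0.5

    def test_inverse_consistency(self):
        lab, geom = self._blob_labels()
        shifted = np.roll(lab, 2, axis=1)
        fwd = register_tissue_maps(lab, shifted, geom)
        bwd = register_tissue_maps(shifted, lab, geom)
        inside = ndimage.binary_erosion(lab > 0, iterations=2)
        resid = fwd[inside] + bwd[inside]
        assert np.linalg.norm(resid, axis=-1).mean() < 0.5
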