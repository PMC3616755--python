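"""Key points, trajectory smoothing, TPS fields and label propagation."""

import numpy as np
import pytest
from scipy import ndimage

from longbrain.grid import ImageGrid
from longbrain.labeling import (DeformationField, KeyPointSet,
                                TrajectoryBundle, compose, match_keypoints,
                                propagate_labels, select_keypoints,
                                smooth_trajectories, tps_field)


@pytest.fixture(scope="module")
def textured():
    rng = np.random.default_rng(5)
    vox = ndimage.gaussian_filter(rng.standard_normal((48, 48, 48)), 2.0)
    vox *= 100.0 / vox.std()
    return ImageGrid(vox.astype(np.float32), origin=(-23.5,) * 3)


class TestKeypoints:
    def test_constant_image_yields_empty_set(self):
        img = ImageGrid(np.full((24, 24, 24), 7.0))
        assert len(select_keypoints(img).points) == 0

    def test_minimum_separation(self, textured):
        kps = select_keypoints(textured, n_per_level=(40, 40), r_min=5.0)
        pts = kps.points
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 5.0

    def test_saliency_sorted_descending(self, textured):
        kps = select_keypoints(textured)
        assert (np.diff(kps.saliency) <= 1e-12).all()

    def test_bright_blob_keypoint_near_gradient_ring(self):
        n = 40
        ii, jj, kk = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
        r2 = (ii - 20.0) ** 2 + (jj - 20.0) ** 2 + (kk - 20.0) ** 2
        sigma = 5.0
        img = ImageGrid(100.0 * np.exp(-r2 / (2 * sigma ** 2)))
        kps = select_keypoints(img, n_per_level=(5,))
        # a Gaussian blob's gradient peaks at radius sigma
        top_r = np.linalg.norm(kps.points[0] - 20.0)
        assert abs(top_r - sigma) <= 2.0


class TestMatching:
    def test_self_match_zero_offset_full_score(self, textured):
        kps = select_keypoints(textured, n_per_level=(30,))
        matches = match_keypoints(textured, textured, kps)
        assert len(matches) > 10
        for p, q, s in matches:
            np.testing.assert_array_equal(p, q)
            assert s > 0.999

    def test_integer_shift_recovered(self, textured):
        shifted = textured.like(np.roll(textured.voxels, 3, axis=1))
        kps = select_keypoints(textured, n_per_level=(30,))
        matches = match_keypoints(textured, shifted, kps)
        offsets = np.array([q - p for p, q, _ in matches])
        med = np.median(offsets, axis=0)
        np.testing.assert_allclose(med, [0, 3, 0], atol=1.0)

    def test_uncorrelated_noise_mostly_rejected(self, textured):
        rng = np.random.default_rng(11)
        noise = textured.like(
            (rng.standard_normal(textured.shape) * 100).astype(np.float32))
        kps = select_keypoints(textured, n_per_level=(40, 40))
        try:
            matches = match_keypoints(textured, noise, kps)
            survived = len(matches)
        except ValueError:
            survived = 0
        assert survived <= 0.1 * len(kps.points)


class TestTrajectorySmoothing:
    def test_constant_trajectory_unchanged(self):
        tb = TrajectoryBundle(np.tile([[1.0, 2.0, 3.0]], (4, 5, 1)))
        out = smooth_trajectories(tb, bandwidth=1.0)
        np.testing.assert_allclose(out.positions, tb.positions)

    def test_outlier_spike_contracted(self):
        pos = np.zeros((1, 5, 3))
        pos[0, 2, 0] = 4.0
        out = smooth_trajectories(TrajectoryBundle(pos), bandwidth=1.0)
        assert np.abs(out.positions).max() < 4.0
        assert out.positions[0, :, 0].var() < pos[0, :, 0].var()

    def test_linear_trajectory_interior_point_preserved(self):
        t = np.arange(5, dtype=float)
        pos = np.stack([t, 2 * t, -t], axis=-1)[None]
        out = smooth_trajectories(TrajectoryBundle(pos), bandwidth=1.0)
        # symmetric weights cancel the linear term at the center point
        np.testing.assert_allclose(out.positions[0, 2], pos[0, 2],
                                   atol=1e-9)

    def test_variance_contraction_per_coordinate(self, rng):
        pos = rng.normal(size=(6, 7, 3))
        out = smooth_trajectories(TrajectoryBundle(pos), bandwidth=1.5)
        assert (out.positions.var(axis=1) <= pos.var(axis=1) + 1e-12).all()


class TestTPS:
    def _geom(self, n=16):
        return ImageGrid(np.zeros((n, n, n)), origin=(-(n - 1) / 2.0,) * 3)

    def test_zero_displacement_gives_zero_field(self, rng):
        src = rng.uniform(-6, 6, (12, 3))
        f = tps_field(src, src, self._geom())
        assert np.abs(f.displacement).max() < 1e-9

    def test_affine_map_reproduced_exactly(self, rng):
        src = rng.uniform(-6, 6, (15, 3))
        A = np.array([[1.05, 0.02, 0.0], [0.0, 0.97, -0.03],
                      [0.01, 0.0, 1.02]])
        b = np.array([0.8, -0.5, 0.3])
        dst = src @ A.T + b
        f = tps_field(src, dst, self._geom())
        g = f.geometry
        ii, jj, kk = np.meshgrid(*[np.arange(n) for n in g.shape],
                                 indexing="ij")
        world = np.stack([ii, jj, kk], axis=-1) * g.spacing + g.origin
        expect = world.reshape(-1, 3) @ A.T + b - world.reshape(-1, 3)
        np.testing.assert_allclose(f.displacement.reshape(-1, 3), expect,
                                   atol=1e-6)

    def test_exact_interpolation_at_control_points(self, rng):
        src = rng.uniform(-6, 6, (10, 3))
        dst = src + rng.normal(0, 0.5, src.shape)
        f = tps_field(src, dst, self._geom())
        from scipy.interpolate import RBFInterpolator
        rbf = RBFInterpolator(src, dst - src, kernel="linear", degree=1)
        np.testing.assert_allclose(rbf(src), dst - src, atol=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            tps_field(np.zeros((3, 3)), np.zeros((3, 3)), self._geom())


class TestComposeAndPropagate:
    def _geom(self, n=20):
        return ImageGrid(np.zeros((n, n, n)), origin=(-(n - 1) / 2.0,) * 3)

    def _translation(self, geom, vec):
        d = np.tile(np.asarray(vec, dtype=np.float32), geom.shape + (1,))
        return DeformationField(d, geom)

    def test_compose_with_zero_is_identity(self, rng):
        geom = self._geom()
        d = rng.normal(0, 0.5, geom.shape + (3,)).astype(np.float32)
        f = DeformationField(d, geom)
        zero = DeformationField.zero(geom)
        out = compose(zero, f)
        # zero first: samples f's displacement at the undisplaced points
        np.testing.assert_allclose(out.displacement, f.displacement,
                                   atol=1e-6)

    def test_translations_add(self):
        geom = self._geom()
        a = self._translation(geom, (1.0, -2.0, 0.5))
        b = self._translation(geom, (0.5, 1.0, 1.5))
        out = compose(a, b)
        np.testing.assert_allclose(
            out.displacement, np.broadcast_to([1.5, -1.0, 2.0],
                                              out.displacement.shape),
            atol=1e-6)

    def test_compose_with_numeric_inverse_near_zero(self):
        geom = self._geom(24)
        rng = np.random.default_rng(2)
        d = np.stack([ndimage.gaussian_filter(
            rng.standard_normal(geom.shape), 4.0) for _ in range(3)],
            axis=-1)
        d *= 1.5 / np.abs(d).max()
        f = DeformationField(d.astype(np.float32), geom)
        out = compose(f, f.invert())
        # interior, away from boundary extrapolation
        mag = np.linalg.norm(out.displacement[4:-4, 4:-4, 4:-4], axis=-1)
        assert mag.mean() < 0.5

    def test_associativity_on_smooth_fields(self):
        geom = self._geom(24)
        rng = np.random.default_rng(3)

        def smooth():
            d = np.stack([ndimage.gaussian_filter(
                rng.standard_normal(geom.shape), 5.0) for _ in range(3)],
                axis=-1)
            return DeformationField((d / np.abs(d).max()).astype(np.float32),
                                    geom)

        f1, f2, f3 = smooth(), smooth(), smooth()
        left = compose(compose(f1, f2), f3)
        right = compose(f1, compose(f2, f3))
        mag = np.linalg.norm(
            left.displacement[4:-4, 4:-4, 4:-4]
            - right.displacement[4:-4, 4:-4, 4:-4], axis=-1)
        assert mag.mean() < 0.1

    def test_zero_field_preserves_labels_exactly(self, rng):
        geom = self._geom()
        labels = geom.like(rng.integers(0, 5, geom.shape).astype(np.int16))
        out = propagate_labels(labels, DeformationField.zero(geom))
        np.testing.assert_array_equal(out.voxels, labels.voxels)

    def test_integer_translation_shifts_labels(self, rng):
        geom = self._geom()
        labels = geom.like(rng.integers(0, 5, geom.shape).astype(np.int16))
        f = self._translation(geom, (2.0, 0.0, 0.0))
        out = propagate_labels(labels, f)
        np.testing.assert_array_equal(out.voxels[:-2], labels.voxels[2:])

    def test_label_set_never_grows(self, rng):
        geom = self._geom()
        labels = geom.like(rng.integers(0, 4, geom.shape).astype(np.int16))
        d = rng.normal(0, 1.0, geom.shape + (3,)).astype(np.float32)
        out = propagate_labels(labels, DeformationField(d, geom))
        assert set(np.unique(out.voxels)) <= set(np.unique(labels.voxels))

    def test_float_labels_rejected(self):
        geom = self._geom()
        with pytest.raises(ValueError):
            propagate_labels(geom.like(np.zeros(geom.shape)),
                             DeformationField.zero(geom))
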