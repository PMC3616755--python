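"""Consistent ROI labeling through groupwise feature-driven registration.

The atlas parcellation reaches every timepoint along a composed deformation
pathway: timepoint -> group mean (estimated jointly for the whole series
with temporal smoothing of key-point trajectories) and group mean -> atlas
(a symmetric pairwise registration).  All dense fields are interpolated from
sparse key-point correspondences by 3-D thin-plate splines (kernel U(r) = r
with an exact affine part), and labels are propagated by nearest-neighbour
pullback so no new label values can appear.

Displacement-field convention: a field is defined on its *source* grid and
maps source world coordinates to target world coordinates,
``target_coord = x + displacement(x)``; pulling the target image onto the
source grid samples it at those coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import RBFInterpolator
from skimage.feature import match_template

from .grid import ImageGrid


@dataclass
class DeformationField:
    """Dense voxelwise displacement in mm on ``geometry``'s grid."""

    displacement: np.ndarray        # shape + (3,)
    geometry: ImageGrid

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=np.float32)
        if not np.isfinite(self.displacement).all():
            raise ValueError("displacement field must be finite")

    @classmethod
    def zero(cls, geometry: ImageGrid) -> "DeformationField":
        return cls(np.zeros(geometry.shape + (3,), dtype=np.float32),
                   geometry)

    def _target_world(self) -> np.ndarray:
        g = self.geometry
        ii, jj, kk = np.meshgrid(*[np.arange(n) for n in g.shape],
                                 indexing="ij")
        world = np.stack([ii, jj, kk], axis=-1) * g.spacing + g.origin
        return world + self.displacement

    def apply(self, img: ImageGrid, order: int = 1,
              cval: float = 0.0) -> ImageGrid:
        """Pull ``img`` (living in target space) onto this field's grid."""
        tgt = self._target_world()
        idx = np.moveaxis((tgt - img.origin) / img.spacing, -1, 0)
        vals = ndimage.map_coordinates(img.voxels, idx, order=order,
                                       mode="constant", cval=cval)
        return self.geometry.like(vals.astype(img.voxels.dtype))

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.displacement, axis=-1)

    def invert(self, iters: int = 20) -> "DeformationField":
        """Fixed-point numeric inverse: d_inv(x) = -d(x + d_inv(x))."""
        g = self.geometry
        inv = np.zeros_like(self.displacement)
        for _ in range(iters):
            probe = DeformationField(inv, g)
            sampled = np.stack(
                [probe.apply(g.like(self.displacement[..., c]),
                             order=1).voxels for c in range(3)], axis=-1)
            inv = -sampled
        return DeformationField(inv, g)


def compose(f_a2b: DeformationField, f_b2c: DeformationField
            ) -> DeformationField:
    """Chain two fields: the composite maps a-space x through
    y = x + d1(x) into z = y + d2(y), with d2 interpolated at y."""
    g = f_a2b.geometry
    y = f_a2b._target_world()
    idx = np.moveaxis((y - f_b2c.geometry.origin) / f_b2c.geometry.spacing,
                      -1, 0)
    d2 = np.stack([ndimage.map_coordinates(
        f_b2c.displacement[..., c], idx, order=1, mode="nearest")
        for c in range(3)], axis=-1)
    return DeformationField(f_a2b.displacement + d2, g)


@dataclass
class KeyPointSet:
    """Salient voxel locations on one image, sorted by decreasing saliency,
    pairwise separated by at least ``r_min`` voxels."""

    points: np.ndarray        # (K, 3) voxel indices
    saliency: np.ndarray      # (K,)
    r_min: float


@dataclass
class TrajectoryBundle:
    """Per key point, its matched world position at every timepoint."""

    positions: np.ndarray     # (K, T, 3) mm


def select_keypoints(img: ImageGrid, n_per_level: tuple[int, ...] = (80, 80),
                     r_min: float = 5.0, border: int = 5) -> KeyPointSet:
    """Hierarchical salient-point selection.

    Saliency is gradient magnitude times local intensity standard deviation,
    evaluated on a Gaussian pyramid (one entry of ``n_per_level`` per level,
    coarse to fine); per level a greedy pick of the top-saliency voxels
    enforces the ``r_min`` minimum separation against all points chosen so
    far, so finer levels fill in where coarse coverage is sparse.
    """
    vox = np.asarray(img.voxels, dtype=np.float64)
    if vox.max() - vox.min() < 1e-12:
        return KeyPointSet(np.zeros((0, 3)), np.zeros(0), r_min)

    chosen, scores = [], []
    levels = len(n_per_level)
    for level in range(levels):
        sigma = 2.0 ** (levels - 1 - level)
        sm = ndimage.gaussian_filter(vox, sigma)
        g = np.gradient(sm)
        gmag = np.sqrt(g[0] ** 2 + g[1] ** 2 + g[2] ** 2)
        local_var = np.maximum(
            ndimage.uniform_filter(sm ** 2, 5)
            - ndimage.uniform_filter(sm, 5) ** 2, 0.0)
        sal = gmag * np.sqrt(local_var)
        # filter/gradient edge artifacts must not become "features"
        if border > 0:
            edge = np.zeros(sal.shape, bool)
            edge[border:-border, border:-border, border:-border] = True
            sal = np.where(edge, sal, 0.0)
        flat = np.argsort(sal, axis=None)[::-1]
        coords = np.column_stack(np.unravel_index(flat[:20000], vox.shape))
        vals = sal.reshape(-1)[flat[:20000]]
        taken = 0
        for c, v in zip(coords, vals):
            if v <= 0 or taken >= n_per_level[level]:
                break
            if chosen and (np.linalg.norm(np.asarray(chosen) - c, axis=1)
                           < r_min).any():
                continue
            chosen.append(c)
            scores.append(v)
            taken += 1
    pts = np.asarray(chosen, dtype=float).reshape(-1, 3)
    sc = np.asarray(scores)
    order = np.argsort(sc)[::-1]
    return KeyPointSet(pts[order], sc[order], r_min)


def _patch(vox: np.ndarray, center: np.ndarray, half: int) -> np.ndarray | None:
    lo = (center - half).astype(int)
    hi = (center + half + 1).astype(int)
    if (lo < 0).any() or (hi > np.asarray(vox.shape)).any():
        return None
    return vox[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]


def match_keypoints(mean: ImageGrid, target: ImageGrid, kps: KeyPointSet,
                    search_radius: int = 8, patch_size: int = 7,
                    ncc_threshold: float = 0.6,
                    mutual_tol: float = 1.0) -> list[tuple]:
    """Best-NCC match of each key point's local patch within a search box.

    A match survives only if its normalized cross-correlation reaches the
    threshold and the backward match from the found position lands within
    ``mutual_tol`` voxels of the original point (mutual-best check).
    Returns (point, matched_point, score) triples in voxel coordinates.
    """
    if mean.shape != target.shape:
        raise ValueError("match_keypoints requires identical geometry")
    mv = np.asarray(mean.voxels, dtype=np.float64)
    tv = np.asarray(target.voxels, dtype=np.float64)
    half = patch_size // 2
    out = []
    for p, s in zip(kps.points, kps.saliency):
        pi = np.round(p).astype(int)
        tpl = _patch(mv, pi, half)
        if tpl is None or tpl.std() < 1e-9:
            continue
        lo = np.maximum(pi - half - search_radius, 0)
        hi = np.minimum(pi + half + search_radius + 1, mv.shape)
        region = tv[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        if min(region.shape) < patch_size or region.std() < 1e-9:
            continue
        ncc = match_template(region, tpl)
        best = np.unravel_index(np.argmax(ncc), ncc.shape)
        score = float(ncc[best])
        if score < ncc_threshold:
            continue
        q = np.asarray(best) + lo + half
        # backward check: match q's patch in a box around p
        tplb = _patch(tv, q, half)
        if tplb is None or tplb.std() < 1e-9:
            continue
        lo2 = np.maximum(q - half - search_radius, 0)
        hi2 = np.minimum(q + half + search_radius + 1, mv.shape)
        region2 = mv[lo2[0]:hi2[0], lo2[1]:hi2[1], lo2[2]:hi2[2]]
        if min(region2.shape) < patch_size:
            continue
        ncc2 = match_template(region2, tplb)
        back = np.asarray(np.unravel_index(np.argmax(ncc2), ncc2.shape)) \
            + lo2 + half
        if np.linalg.norm(back - pi) > mutual_tol:
            continue
        out.append((pi.astype(float), q.astype(float), score))
    if not out:
        raise ValueError("no key-point matches survived; matching is "
                         "degenerate")
    return out


def smooth_trajectories(tb: TrajectoryBundle, bandwidth: float = 1.0
                        ) -> TrajectoryBundle:
    """Nadaraya-Watson Gaussian kernel smoothing along each trajectory.

    The bandwidth is in units of timepoint index; a single timepoint (or a
    non-positive bandwidth) returns the input unchanged.
    """
    pos = tb.positions
    nt = pos.shape[1]
    if nt <= 1 or bandwidth <= 0:
        return TrajectoryBundle(pos.copy())
    t = np.arange(nt)
    wgt = np.exp(-0.5 * ((t[:, None] - t[None, :]) / bandwidth) ** 2)
    wgt /= wgt.sum(axis=1, keepdims=True)
    return TrajectoryBundle(np.einsum("st,kti->ksi", wgt, pos))


def tps_field(control_src: np.ndarray, control_dst: np.ndarray,
              geometry: ImageGrid, regularization: float = 0.0
              ) -> DeformationField:
    """Dense displacement by 3-D thin-plate-spline interpolation.

    Standard polyharmonic spline with kernel U(r) = r and a full affine
    part; zero regularization interpolates the control displacements
    exactly and reproduces an affine map exactly.  Control points are in mm.
    """
    src = np.asarray(control_src, dtype=np.float64)
    dst = np.asarray(control_dst, dtype=np.float64)
    if len(src) < 4:
        raise ValueError("need at least 4 control points")
    disp = dst - src
    try:
        rbf = RBFInterpolator(src, disp, kernel="linear", degree=1,
                              smoothing=float(regularization))
    except np.linalg.LinAlgError:
        rbf = RBFInterpolator(src, disp, kernel="linear", degree=1,
                              smoothing=max(regularization, 1e-6))
    g = geometry
    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in g.shape], indexing="ij")
    world = (np.stack([ii, jj, kk], axis=-1) * g.spacing
             + g.origin).reshape(-1, 3)
    dense = rbf(world).reshape(g.shape + (3,))
    return DeformationField(dense, g)


def groupwise_register(series: list[ImageGrid], rounds: int = 5,
                       bandwidth: float = 1.0,
                       n_per_level: tuple[int, ...] = (80, 80),
                       search_radius: int = 8,
                       ncc_threshold: float = 0.6
                       ) -> tuple[list[DeformationField], ImageGrid]:
    """Groupwise nonrigid registration of an affine-prealigned series.

    Per round: select key points on the current mean; match them into every
    timepoint; assemble per-key-point temporal trajectories and kernel-smooth
    them; recenter the trajectories so their temporal average displacement is
    zero (unbiased common space); interpolate one TPS field per timepoint;
    warp the images back to the mean frame and re-average the mean.

    Returns one field per timepoint, defined on the mean grid and mapping
    mean coordinates to that timepoint (mean-grid pullback of the images),
    plus the final group-mean image.
    """
    nt = len(series)
    ref = series[0]
    mean = ref.like(np.mean([s.voxels for s in series], axis=0)
                    .astype(np.float32))
    fields = [DeformationField.zero(ref) for _ in range(nt)]

    for _ in range(int(rounds)):
        kps = select_keypoints(mean, n_per_level=n_per_level)
        if len(kps.points) < 4:
            raise ValueError("too few key points on the group mean")
        matched_pts, matched_targets = None, []
        common = None
        per_t = []
        for t in range(nt):
            matches = match_keypoints(mean, series[t], kps,
                                      search_radius=search_radius,
                                      ncc_threshold=ncc_threshold)
            d = {tuple(np.round(p).astype(int)): q for p, q, _ in matches}
            per_t.append(d)
            keys = set(d)
            common = keys if common is None else (common & keys)
        common = sorted(common)
        if len(common) < 4:
            raise ValueError("too few key points matched at every timepoint")
        src_idx = np.asarray(common, dtype=float)
        src_mm = ref.index_to_world(src_idx)
        traj = np.stack([ref.index_to_world(
            np.asarray([per_t[t][k] for k in common]))
            for t in range(nt)], axis=1)          # (K, T, 3)
        traj = smooth_trajectories(TrajectoryBundle(traj),
                                   bandwidth).positions
        # unbiased common space: temporal mean of each trajectory returns
        # to its key point
        traj = traj - (traj.mean(axis=1, keepdims=True)
                       - src_mm[:, None, :])

        fields = [tps_field(src_mm, traj[:, t, :], ref) for t in range(nt)]
        warped = [fields[t].apply(series[t]) for t in range(nt)]
        mean = ref.like(np.mean([w.voxels for w in warped], axis=0)
                        .astype(np.float32))
    return fields, mean


def register_atlas_to_mean(atlas: ImageGrid, mean: ImageGrid,
                           n_per_level: tuple[int, ...] = (80, 80),
                           search_radius: int = 8,
                           ncc_threshold: float = 0.6
                           ) -> DeformationField:
    """Symmetric pairwise registration of the atlas onto the group mean.

    The key-point/NCC/TPS machinery runs in both directions; the backward
    field is numerically inverted and averaged with the forward one.
    Returns a field on the mean grid mapping mean coordinates into the
    atlas (the pullback that warps the atlas onto the mean).
    """
    def _one_way(fixed, moving):
        kps = select_keypoints(fixed, n_per_level=n_per_level)
        matches = match_keypoints(fixed, moving, kps,
                                  search_radius=search_radius,
                                  ncc_threshold=ncc_threshold)
        src = fixed.index_to_world(np.asarray([p for p, _, _ in matches]))
        dst = moving.index_to_world(np.asarray([q for _, q, _ in matches]))
        return tps_field(src, dst, fixed)

    fwd = _one_way(mean, atlas)              # mean grid -> atlas coords
    bwd = _one_way(atlas, mean)              # atlas grid -> mean coords
    bwd_inv = bwd.invert()                   # mean grid -> atlas coords
    avg = 0.5 * (fwd.displacement + bwd_inv.displacement)
    return DeformationField(avg, mean)


def propagate_labels(labels: ImageGrid, field: DeformationField
                     ) -> ImageGrid:
    """Nearest-neighbour pullback of an integer label volume through a
    field; the output label set is a subset of the input's."""
    lab = np.asarray(labels.voxels)
    if not np.issubdtype(lab.dtype, np.integer):
        raise ValueError("labels must be integer-valued")
    return field.apply(labels, order=0, cval=0)
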