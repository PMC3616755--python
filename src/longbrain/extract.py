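"""Consistent 4D skull stripping with coupled deformable surfaces.

One closed surface per timepoint, all sharing a fixed icosphere topology, is
evolved simultaneously.  Four forces act on every vertex: (1) a spatial
smoothness force toward the one-ring centroid, split into a fully applied
tangential part and a curvature-attenuated normal part; (2) a BET-style
image-intensity force probing local min/max intensities along the inward
normal against adaptive thresholds; (3) a brain-probability force pushing
along the normal by P - 1/2; and (4) a temporal smoothness force pulling
each vertex toward the mean position of the same vertex at the neighbouring
timepoints.  With the temporal weight at zero the scheme reduces exactly
(bit for bit) to independent per-timepoint 3D evolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import csr_matrix

from .grid import ImageGrid
from .mesh import SurfaceMesh, has_self_intersections, mesh_to_mask, tessellate_sphere
from .registration import (apply_affine, groupwise_affine, warp_map_pair,
                           warp_probability_map)


@dataclass
class SphereEstimate:
    """Initial brain envelope: center of gravity and equivalent-volume
    radius."""

    cog: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.cog = np.asarray(self.cog, dtype=float)
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass
class ForceWeights:
    """Weights and schedule of the four vertex forces.

    ``step_size`` is in mm per unit force; ``iters`` follows the classic
    1000-iteration convention for surface-based stripping.
    """

    w_smooth: float = 1.0
    w_intensity: float = 0.3
    w_prob: float = 0.3
    w_temporal: float = 0.5
    step_size: float = 0.1
    iters: int = 1000
    # intensity-force probe depths (mm) and fractional threshold
    d_min: float = 7.0
    d_max: float = 3.0
    bt: float = 0.5
    # curvature sigmoid: attenuate the normal smoothing component between
    # radii of curvature r_min and r_max (mm), as in classic BET
    r_min: float = 3.33
    r_max: float = 10.0

    def __post_init__(self) -> None:
        if min(self.w_smooth, self.w_intensity, self.w_prob,
               self.w_temporal) < 0:
            raise ValueError("force weights must be nonnegative")


@dataclass
class SurfaceSeries:
    """One mesh per timepoint, identical triangle arrays throughout."""

    meshes: list

    def __post_init__(self) -> None:
        tris = self.meshes[0].triangles
        for m in self.meshes[1:]:
            if m.triangles is not tris and not np.array_equal(m.triangles, tris):
                raise ValueError("all meshes must share the same topology")


def estimate_sphere(img: ImageGrid, mask: np.ndarray) -> SphereEstimate:
    """Sphere summarizing a roughly brain-shaped masked region.

    Center = intensity-weighted centroid of the masked voxels (invariant to
    global intensity scaling); radius = radius of the ball with the mask's
    volume, (3 V / 4 pi)^(1/3).
    """
    m = np.asarray(mask) > 0
    if not m.any():
        raise ValueError("estimate_sphere requires a nonempty mask")
    w = np.asarray(img.voxels, dtype=np.float64)[m]
    w = np.maximum(w, 0.0)
    if w.sum() <= 0:
        w = np.ones_like(w)
    idx = np.argwhere(m).astype(np.float64)
    cog_idx = (idx * w[:, None]).sum(axis=0) / w.sum()
    cog = img.index_to_world(cog_idx)
    volume = m.sum() * float(np.prod(img.spacing))
    radius = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    return SphereEstimate(cog, radius)


def common_sphere(estimates: list[SphereEstimate]) -> SphereEstimate:
    """Arithmetic mean of COGs and radii across timepoints."""
    if not estimates:
        raise ValueError("need at least one sphere estimate")
    cog = np.mean([e.cog for e in estimates], axis=0)
    radius = float(np.mean([e.radius for e in estimates]))
    return SphereEstimate(cog, radius)


def _adjacency(mesh: SurfaceMesh) -> csr_matrix:
    rows, cols, vals = [], [], []
    for i, nb in enumerate(mesh.neighbors):
        rows.extend([i] * len(nb))
        cols.extend(nb.tolist())
        vals.extend([1.0 / len(nb)] * len(nb))
    n = len(mesh.vertices)
    return csr_matrix((vals, (rows, cols)), shape=(n, n))


def _sample(img: ImageGrid, points_mm: np.ndarray) -> np.ndarray:
    idx = (points_mm - img.origin) / img.spacing
    return ndimage.map_coordinates(
        img.voxels.astype(np.float32), idx.reshape(-1, 3).T,
        order=1, mode="nearest").reshape(points_mm.shape[:-1])


@dataclass
class _Thresholds:
    t2: float
    t98: float
    t: float
    tm: float


def _intensity_thresholds(img: ImageGrid, mask: np.ndarray) -> _Thresholds:
    vals = np.asarray(img.voxels, dtype=np.float64)
    pos = vals[vals > 0]
    if pos.size == 0:
        return _Thresholds(0.0, 1.0, 0.1, 0.5)
    inside = vals[np.asarray(mask) > 0]
    t2, t98 = np.percentile(pos, [2, 98])
    t = t2 + 0.1 * (t98 - t2)
    tm = float(np.median(inside)) if inside.size else float(0.5 * (t2 + t98))
    return _Thresholds(float(t2), float(t98), float(t), tm)


def _vertex_update(mesh: SurfaceMesh, img: ImageGrid, prob: ImageGrid,
                   th: _Thresholds, w: ForceWeights, adj: csr_matrix,
                   mean_edge: float) -> np.ndarray:
    """Spatial part of the displacement (smoothness + intensity + prob)."""
    v = mesh.vertices
    normals = mesh.vertex_normals()
    s = adj @ v - v
    sn_mag = np.einsum("ij,ij->i", s, normals)
    sn = sn_mag[:, None] * normals
    st = s - sn

    # curvature-based sigmoid attenuation of the normal component
    rcurv = (mean_edge ** 2) / (2.0 * np.abs(sn_mag) + 1e-9)
    E = 0.5 * (1.0 / w.r_min + 1.0 / w.r_max)
    F = 6.0 / (1.0 / w.r_min - 1.0 / w.r_max)
    f2 = 0.5 * (1.0 + np.tanh(F * (1.0 / rcurv - E)))
    u_smooth = 0.5 * st + f2[:, None] * sn

    normal_force = np.zeros(len(v))
    if w.w_intensity > 0:
        # intensity force: probe inward along -n
        depths_min = np.arange(0.0, w.d_min + 1e-9, 1.0)
        depths_max = np.arange(0.0, w.d_max + 1e-9, 1.0)
        pts = v[None, :, :] - depths_min[:, None, None] * normals[None, :, :]
        vals = _sample(img, pts)                    # (D, V)
        n_max = len(depths_max)
        imin = np.clip(vals.min(axis=0), th.t2, th.tm)
        imax = np.clip(vals[:n_max].max(axis=0), th.t, th.t98)
        tl = (imax - th.t2) * w.bt + th.t2
        f3 = 2.0 * (imin - tl) / np.maximum(imax - th.t2, 1e-9)
        normal_force = normal_force + w.w_intensity * np.clip(f3, -1.0, 1.0)
    if w.w_prob > 0:
        p = np.clip(_sample(prob, v[None]), 0.0, 1.0)[0]
        normal_force = normal_force + w.w_prob * (p - 0.5)
    return w.w_smooth * u_smooth + normal_force[:, None] * normals


def evolve_surface_3d(img: ImageGrid, prob: ImageGrid, init: SurfaceMesh,
                      w: ForceWeights, mask: np.ndarray | None = None
                      ) -> SurfaceMesh:
    """Independent single-timepoint surface evolution (the 3D reduction)."""
    th = _intensity_thresholds(
        img, mask if mask is not None else prob.voxels >= 0.5)
    adj = _adjacency(init)
    mesh = init.with_vertices(init.vertices.copy())
    edges = np.linalg.norm(
        mesh.vertices[mesh.triangles[:, 0]]
        - mesh.vertices[mesh.triangles[:, 1]], axis=1)
    mean_edge = float(edges.mean())
    for _ in range(int(w.iters)):
        u = _vertex_update(mesh, img, prob, th, w, adj, mean_edge)
        mesh.vertices = mesh.vertices + w.step_size * u
    return mesh


def evolve_surfaces_4d(series: list[ImageGrid], probs: list[ImageGrid],
                       init: SurfaceSeries, w: ForceWeights,
                       masks: list[np.ndarray] | None = None
                       ) -> SurfaceSeries:
    """Simultaneous evolution of all timepoints' surfaces.

    Per iteration the spatial forces are computed per timepoint exactly as in
    :func:`evolve_surface_3d`; the temporal force pulls vertex i of timepoint
    t toward the mean of vertex i at the immediate temporal neighbours
    (endpoints use their single neighbour), evaluated on the pre-iteration
    state so the scheme is symmetric in time.  A self-intersection screen at
    the end sets ``warning`` flags but never fails.
    """
    nt = len(series)
    if len(probs) != nt or len(init.meshes) != nt:
        raise ValueError("series, probs and init must have equal length")
    ths = [_intensity_thresholds(
        img, masks[t] if masks is not None else probs[t].voxels >= 0.5)
        for t, img in enumerate(series)]
    adj = _adjacency(init.meshes[0])
    meshes = [m.with_vertices(m.vertices.copy()) for m in init.meshes]
    edges = np.linalg.norm(
        meshes[0].vertices[meshes[0].triangles[:, 0]]
        - meshes[0].vertices[meshes[0].triangles[:, 1]], axis=1)
    mean_edge = float(edges.mean())

    for _ in range(int(w.iters)):
        spatial = [
            _vertex_update(meshes[t], series[t], probs[t], ths[t], w, adj,
                           mean_edge)
            for t in range(nt)]
        if w.w_temporal > 0 and nt > 1:
            snapshot = [m.vertices for m in meshes]
            for t in range(nt):
                nb = [snapshot[j] for j in (t - 1, t + 1) if 0 <= j < nt]
                t_mean = np.mean(nb, axis=0)
                spatial[t] = spatial[t] + w.w_temporal * (t_mean - snapshot[t])
        for t in range(nt):
            meshes[t].vertices = meshes[t].vertices + w.step_size * spatial[t]

    out = SurfaceSeries(meshes)
    out.warnings = [has_self_intersections(m) for m in meshes]
    return out


@dataclass
class ExtractionResult:
    """Everything the 4D extraction stage produces."""

    brain_masks: list          # native-space binary ImageGrids
    brain_images: list         # native-space masked intensity ImageGrids
    surfaces: SurfaceSeries    # in common affine space
    affines: list              # 4x4 native -> common
    group_mean: ImageGrid
    warped_probs: list = field(default_factory=list)


def extract_series(series: list[ImageGrid], atlas_template: ImageGrid,
                   brain_probability: ImageGrid, w: ForceWeights | None = None,
                   subdivisions: int = 3, groupwise_iters: int = 2
                   ) -> ExtractionResult:
    """Full 4D skull stripping of a preprocessed series.

    Pipeline: groupwise affine alignment to an unbiased common space; warp
    the atlas brain-probability map onto each aligned timepoint (affine +
    demons, driven by the atlas template); strip by probability >= 1/2;
    estimate one sphere per timepoint and average into a common initial
    sphere; evolve all surfaces jointly; rasterize each final surface in its
    timepoint's native space.
    """
    w = w or ForceWeights()
    if len(series) >= 2:
        to_common, mean = groupwise_affine(series, iters=groupwise_iters)
    else:
        to_common, mean = [np.eye(4)], series[0]
    ref = series[0]
    warped = [apply_affine(s, np.linalg.inv(a), ref)
              for s, a in zip(series, to_common)]

    probs = [warp_probability_map(brain_probability, wi,
                                  template=atlas_template) for wi in warped]
    strip_masks = [p.voxels >= 0.5 for p in probs]
    spheres = [estimate_sphere(wi, m) for wi, m in zip(warped, strip_masks)]
    sphere = common_sphere(spheres)
    init_mesh = tessellate_sphere(sphere.cog, sphere.radius,
                                  subdivisions=subdivisions)
    init = SurfaceSeries([init_mesh.with_vertices(init_mesh.vertices.copy())
                          for _ in series])
    evolved = evolve_surfaces_4d(warped, probs, init, w, masks=strip_masks)

    brain_masks, brain_images = [], []
    for t, img in enumerate(series):
        # move the common-space mesh into this timepoint's native frame
        a_inv = np.linalg.inv(to_common[t])
        v_nat = evolved.meshes[t].vertices @ a_inv[:3, :3].T + a_inv[:3, 3]
        nat_mesh = evolved.meshes[t].with_vertices(v_nat)
        mask = mesh_to_mask(nat_mesh, img)
        brain_masks.append(mask)
        brain_images.append(img.like(
            np.where(mask.voxels > 0, img.voxels, 0.0).astype(np.float32)))
    return ExtractionResult(brain_masks, brain_images, evolved, to_common,
                            mean, probs)


def remove_cerebellum(brain_images: list[ImageGrid],
                      brain_masks: list[ImageGrid],
                      atlas_template: ImageGrid,
                      cereb_mask: ImageGrid,
                      groupwise_iters: int = 2) -> list[ImageGrid]:
    """Subtract the atlas cerebellum mask from every timepoint's brain mask.

    The brain-extracted images are groupwise affine-aligned; the atlas is
    registered (affine + demons) onto their mean; the cerebellum mask rides
    through those transforms and is then carried into each timepoint's
    native frame through the inverse of its groupwise affine.
    """
    if np.count_nonzero(cereb_mask.voxels) == 0:
        return [m.like(m.voxels.copy()) for m in brain_masks]
    if len(brain_images) >= 2:
        to_common, mean = groupwise_affine(brain_images,
                                           iters=groupwise_iters)
    else:
        to_common, mean = [np.eye(4)], brain_images[0]
    _, cereb_on_mean = warp_map_pair(atlas_template, cereb_mask, mean,
                                     order=0)
    out = []
    for msk, a in zip(brain_masks, to_common):
        # native voxel x looks up the mean-space mask at (to_common @ x)
        cereb_nat = apply_affine(cereb_on_mean, a, msk, order=0)
        cleaned = (np.asarray(msk.voxels) > 0) & ~(cereb_nat.voxels > 0)
        out.append(msk.like(cleaned.astype(np.uint8)))
    return out
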