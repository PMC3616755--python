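"""Closed triangle meshes: icosphere tessellation, rasterization, checks.

The deformable skull-stripping surfaces are closed 2-manifold triangle
meshes with fixed topology; vertex i keeps its identity across timepoints
and across evolution iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .grid import ImageGrid


@dataclass
class SurfaceMesh:
    """Closed triangle mesh in world RAS mm.

    ``neighbors`` is a ragged list: for vertex i the sorted indices of its
    one-ring.  The triangle array is shared (not copied) when meshes are
    deformed, so a series of evolved meshes keeps identical topology.
    """

    vertices: np.ndarray      # (V, 3) float
    triangles: np.ndarray     # (F, 3) int
    neighbors: list | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.neighbors is None:
            self.neighbors = _one_rings(self.triangles, len(self.vertices))

    @property
    def euler_characteristic(self) -> int:
        edges = set()
        for tri in self.triangles:
            for a, b in ((0, 1), (1, 2), (2, 0)):
                edges.add((min(tri[a], tri[b]), max(tri[a], tri[b])))
        return len(self.vertices) - len(edges) + len(self.triangles)

    def with_vertices(self, vertices: np.ndarray) -> "SurfaceMesh":
        return SurfaceMesh(vertices, self.triangles, self.neighbors)

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted outward vertex normals (unit length)."""
        v, t = self.vertices, self.triangles
        fn = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        vn = np.zeros_like(v)
        for c in range(3):
            np.add.at(vn, t[:, c], fn)
        norm = np.linalg.norm(vn, axis=1, keepdims=True)
        return vn / np.maximum(norm, 1e-12)

    def is_closed(self) -> bool:
        tm = trimesh.Trimesh(self.vertices, self.triangles, process=False)
        return bool(tm.is_watertight)

    def mean_radius(self, center: np.ndarray | None = None) -> float:
        c = self.vertices.mean(axis=0) if center is None else center
        return float(np.linalg.norm(self.vertices - c, axis=1).mean())


def _one_rings(triangles: np.ndarray, n_vertices: int) -> list:
    rings = [set() for _ in range(n_vertices)]
    for a, b, c in triangles:
        rings[a].update((b, c))
        rings[b].update((a, c))
        rings[c].update((a, b))
    return [np.array(sorted(r), dtype=np.int64) for r in rings]


def tessellate_sphere(cog: np.ndarray, radius: float,
                      subdivisions: int = 4) -> SurfaceMesh:
    """Icosahedron subdivided ``subdivisions`` times, projected to a sphere.

    Vertex count is 10 * 4**subdivisions + 2; every vertex lies exactly at
    distance ``radius`` from ``cog``.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    v = np.asarray(ico.vertices, dtype=np.float64)
    v /= np.linalg.norm(v, axis=1, keepdims=True)  # exact projection
    v = v * radius + np.asarray(cog, dtype=np.float64)
    return SurfaceMesh(v, np.asarray(ico.faces))


def mesh_to_mask(mesh: SurfaceMesh, geom: ImageGrid) -> ImageGrid:
    """Binary mask of voxel centers strictly inside a closed surface.

    Scan-conversion by ray parity: for every (i, j) voxel column the z-ray
    through the voxel centers collects its intersections with the mesh and
    voxels between successive crossing pairs are inside.
    """
    if not mesh.is_closed():
        raise ValueError("mesh_to_mask requires a closed mesh")
    # vertices in continuous voxel-index coordinates
    vidx = geom.world_to_index(mesh.vertices)
    # deterministic tiny shear avoids rays hitting edges/vertices exactly
    vidx = vidx + np.array([1.31e-6, 2.17e-6, 0.0])

    nx, ny, nz = geom.shape
    crossings: dict[tuple[int, int], list[float]] = {}
    tri = vidx[mesh.triangles]  # (F, 3, 3)
    for p0, p1, p2 in tri:
        imin = max(int(np.ceil(min(p0[0], p1[0], p2[0]))), 0)
        imax = min(int(np.floor(max(p0[0], p1[0], p2[0]))), nx - 1)
        jmin = max(int(np.ceil(min(p0[1], p1[1], p2[1]))), 0)
        jmax = min(int(np.floor(max(p0[1], p1[1], p2[1]))), ny - 1)
        if imin > imax or jmin > jmax:
            continue
        d1 = p1[:2] - p0[:2]
        d2 = p2[:2] - p0[:2]
        det = d1[0] * d2[1] - d1[1] * d2[0]
        if abs(det) < 1e-15:
            continue
        gi, gj = np.meshgrid(np.arange(imin, imax + 1),
                             np.arange(jmin, jmax + 1), indexing="ij")
        rx = gi - p0[0]
        ry = gj - p0[1]
        a = (rx * d2[1] - ry * d2[0]) / det
        b = (d1[0] * ry - d1[1] * rx) / det
        inside = (a >= 0) & (b >= 0) & (a + b <= 1)
        if not inside.any():
            continue
        z = p0[2] + a * (p1[2] - p0[2]) + b * (p2[2] - p0[2])
        for i, j, zz in zip(gi[inside], gj[inside], z[inside]):
            crossings.setdefault((int(i), int(j)), []).append(float(zz))

    mask = np.zeros(geom.shape, dtype=np.uint8)
    zs = np.arange(nz)
    for (i, j), cs in crossings.items():
        cs.sort()
        for lo, hi in zip(cs[0::2], cs[1::2]):
            sel = (zs > lo) & (zs < hi)
            mask[i, j, sel] = 1
    return geom.like(mask)


def has_self_intersections(mesh: SurfaceMesh) -> bool:
    """Cheap self-intersection screen; used only to set a warning flag.

    Broad phase: KD-tree query for triangle-centroid pairs closer than the
    largest triangle diameter that share no vertex and whose bounding boxes
    overlap.  A surface evolved under a positive smoothing force essentially
    never folds, so a broad-phase hit is rare and conservative.
    """
    from scipy.spatial import cKDTree

    tri = mesh.vertices[mesh.triangles]            # (F, 3, 3)
    cent = tri.mean(axis=1)
    radii = np.linalg.norm(tri - cent[:, None, :], axis=2).max(axis=1)
    tree = cKDTree(cent)
    pairs = tree.query_pairs(2.0 * radii.max(), output_type="ndarray")
    if len(pairs) == 0:
        return False
    t = mesh.triangles
    share = (t[pairs[:, 0], :, None] == t[pairs[:, 1], None, :]).any(axis=(1, 2))
    cand = pairs[~share]
    if len(cand) == 0:
        return False
    lo = tri.min(axis=1)
    hi = tri.max(axis=1)
    overlap = ((lo[cand[:, 0]] <= hi[cand[:, 1]]) &
               (lo[cand[:, 1]] <= hi[cand[:, 0]])).all(axis=1)
    # require the centroids to actually be closer than the *local* scale
    close = (np.linalg.norm(cent[cand[:, 0]] - cent[cand[:, 1]], axis=1)
             < 0.5 * (radii[cand[:, 0]] + radii[cand[:, 1]]))
    return bool(np.any(overlap & close))
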