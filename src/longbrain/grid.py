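"""Volume container, orientation handling and resampling to the standard space.

Every stage of the pipeline consumes and produces :class:`ImageGrid` objects:
a 3-D scalar array plus the affine geometry (spacing, origin, direction) that
places voxel indices into the world RAS frame (axes pointing Right, Anterior,
Superior, in mm).  Conventions: 0-based voxel indices, voxel-*center* affine,

    world = direction @ diag(spacing) @ index + origin.

Input volumes may arrive in any orientation; they are reoriented to RAS (all
24 right-handed axis permutations/flips are enumerable) and resampled to a
configurable standard geometry (1 mm isotropic, 256 cubed by default; tests
and phantom experiments use a smaller standard).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy import ndimage


@dataclass
class ImageGrid:
    """One 3-D scalar volume with world geometry.

    Attributes
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Scalar intensities, arbitrary units.
    spacing : ndarray, shape (3,)
        Voxel edge lengths in mm, strictly positive.
    origin : ndarray, shape (3,)
        World coordinate (mm) of voxel (0, 0, 0).
    direction : ndarray, shape (3, 3)
        Orthonormal matrix mapping voxel axes to world RAS axes.
    orientation_known : bool
        False for Analyze images without orientation metadata; such images
        must be reoriented explicitly before entering the pipeline.
    """

    voxels: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))
    orientation_known: bool = True

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D array")
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing components must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm map (voxel-center convention)."""
        a = np.eye(4)
        a[:3, :3] = self.direction @ np.diag(self.spacing)
        a[:3, 3] = self.origin
        return a

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        index = np.asarray(index, dtype=float)
        return index @ (self.direction @ np.diag(self.spacing)).T + self.origin

    def world_to_index(self, world: np.ndarray) -> np.ndarray:
        world = np.asarray(world, dtype=float)
        inv = np.linalg.inv(self.direction @ np.diag(self.spacing))
        return (world - self.origin) @ inv.T

    def like(self, voxels: np.ndarray) -> "ImageGrid":
        """New grid with the same geometry but different voxel data."""
        if voxels.shape != self.voxels.shape:
            raise ValueError("voxel shape mismatch")
        return replace(self, voxels=voxels)

    def copy(self) -> "ImageGrid":
        return ImageGrid(self.voxels.copy(), self.spacing.copy(),
                         self.origin.copy(), self.direction.copy(),
                         self.orientation_known)


def _perm_sign(perm) -> int:
    p = list(perm)
    sign = 1
    for i in range(3):
        for j in range(i + 1, 3):
            if p[i] > p[j]:
                sign = -sign
    return sign


@dataclass(frozen=True)
class Orientation:
    """A right-handed relabelling of the voxel axes.

    ``axis_permutation[a]`` is the input axis that becomes output axis ``a``;
    ``axis_flips[a]`` is -1 if that axis is reversed.  Right-handedness
    (permutation sign times the product of flips equal to +1) is enforced.
    """

    axis_permutation: tuple[int, int, int]
    axis_flips: tuple[int, int, int]

    def __post_init__(self) -> None:
        if sorted(self.axis_permutation) != [0, 1, 2]:
            raise ValueError("axis_permutation must permute (0, 1, 2)")
        if any(f not in (-1, 1) for f in self.axis_flips):
            raise ValueError("axis_flips entries must be +/-1")
        if _perm_sign(self.axis_permutation) * int(np.prod(self.axis_flips)) != 1:
            raise ValueError("orientation must be right-handed")

    @property
    def matrix(self) -> np.ndarray:
        """Signed permutation matrix M with index_new = M^T applied semantics.

        Column ``a`` holds the signed unit vector of the input axis feeding
        output axis ``a``; det(M) = +1 by the right-handedness invariant.
        """
        m = np.zeros((3, 3))
        for a in range(3):
            m[self.axis_permutation[a], a] = self.axis_flips[a]
        return m


IDENTITY_ORIENTATION = Orientation((0, 1, 2), (1, 1, 1))


def enumerate_orientations() -> list[Orientation]:
    """All 24 right-handed orientations, in deterministic lexicographic order."""
    out = []
    for perm in itertools.permutations(range(3)):
        for flips in itertools.product((1, -1), repeat=3):
            if _perm_sign(perm) * flips[0] * flips[1] * flips[2] == 1:
                out.append(Orientation(perm, flips))
    return out


def reorient(img: ImageGrid, o: Orientation) -> ImageGrid:
    """Permute/flip the voxel array while keeping world coordinates fixed.

    The direction matrix and origin are updated so that every voxel keeps its
    world position; the multiset of voxel values is preserved exactly.
    """
    v = np.transpose(img.voxels, o.axis_permutation)
    flip_axes = tuple(a for a in range(3) if o.axis_flips[a] == -1)
    if flip_axes:
        v = np.flip(v, axis=flip_axes)
    v = np.ascontiguousarray(v)

    # Output voxel i' corresponds to input voxel i with
    # i[perm[a]] = i'[a] (or reversed when flipped).
    new_spacing = img.spacing[list(o.axis_permutation)]
    m = o.matrix
    lin = img.direction @ np.diag(img.spacing)
    new_lin = lin @ m
    # flipped axes start from the far end of the input axis
    offset = np.zeros(3)
    for a in range(3):
        if o.axis_flips[a] == -1:
            src = o.axis_permutation[a]
            offset += lin[:, src] * (img.voxels.shape[src] - 1)
    new_origin = img.origin + offset
    new_direction = new_lin @ np.diag(1.0 / new_spacing)
    return ImageGrid(v, new_spacing, new_origin, new_direction,
                     orientation_known=True)


def canonical_orientation(img: ImageGrid) -> Orientation:
    """The orientation whose application brings ``img`` closest to RAS.

    Chooses, among the 24 right-handed candidates, the one maximizing the
    trace of the reoriented direction matrix (identity direction wins).
    Requires orientation metadata (``orientation_known``).
    """
    if not img.orientation_known:
        raise ValueError(
            "image has no orientation metadata; pass an explicit Orientation")
    best, best_score = None, -np.inf
    for o in enumerate_orientations():
        score = np.trace(img.direction @ o.matrix)
        if score > best_score + 1e-12:
            best, best_score = o, score
    return best


def to_ras(img: ImageGrid, orientation: Orientation | None = None) -> ImageGrid:
    """Reorient to RAS, either automatically (metadata) or explicitly."""
    o = orientation if orientation is not None else canonical_orientation(img)
    return reorient(img, o)


@dataclass(frozen=True)
class StandardSpace:
    """Target geometry for :func:`resample_standard`.

    The full-size profile is 1 mm isotropic on a 256-cubed grid; phantom
    experiments use the same spacing on a smaller grid.
    """

    shape: tuple[int, int, int] = (256, 256, 256)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)


TEST_STANDARD = StandardSpace(shape=(96, 96, 96))


def resample_standard(img: ImageGrid, standard: StandardSpace = StandardSpace()
                      ) -> ImageGrid:
    """Trilinearly resample an RAS image onto the standard grid.

    The output grid is centered on the input field of view; voxels falling
    outside the input field of view are zero.
    """
    if not np.allclose(img.direction, np.eye(3), atol=1e-6):
        raise ValueError("resample_standard expects an RAS-canonical image")
    shape = np.asarray(standard.shape, dtype=int)
    spacing = np.asarray(standard.spacing, dtype=float)

    in_center = img.index_to_world((np.asarray(img.shape) - 1) / 2.0)
    origin = in_center - spacing * (shape - 1) / 2.0

    out = ImageGrid(np.zeros(tuple(shape), dtype=np.float32),
                    spacing, origin, np.eye(3))
    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    world = np.stack([ii, jj, kk], axis=-1) * spacing + origin
    src_idx = (world - img.origin) / img.spacing
    vals = ndimage.map_coordinates(
        img.voxels.astype(np.float32), np.moveaxis(src_idx, -1, 0),
        order=1, mode="constant", cval=0.0)
    out.voxels = vals.astype(np.float32)
    return out


# ---------------------------------------------------------------------------
# File I/O


class VolumeFormatError(ValueError):
    """Unreadable, truncated or unsupported volume file."""


def read_volume(path) -> ImageGrid:
    """Read a NIfTI-1 (.nii/.nii.gz) or Analyze 7.5 (.hdr/.img) volume.

    Analyze files carry no orientation information; they are loaded with an
    identity direction and flagged (``orientation_known=False``) so that the
    caller must reorient them explicitly.
    """
    try:
        im = nib.load(str(path))
    except Exception as exc:  # nibabel raises a zoo of error types
        raise VolumeFormatError(f"cannot read volume {path!r}: {exc}") from exc
    data = np.asanyarray(im.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeFormatError(f"expected a 3-D volume, got shape {data.shape}")

    is_analyze = isinstance(im, nib.AnalyzeImage) and not isinstance(
        im, nib.Nifti1Image)
    zooms = np.asarray(im.header.get_zooms()[:3], dtype=float)
    if np.any(zooms <= 0):
        zooms = np.where(zooms <= 0, 1.0, zooms)
    if is_analyze:
        return ImageGrid(data, zooms, np.zeros(3), np.eye(3),
                         orientation_known=False)

    aff = im.affine
    lin = aff[:3, :3]
    spacing = np.linalg.norm(lin, axis=0)
    if np.any(spacing <= 0):
        raise VolumeFormatError("degenerate affine in NIfTI header")
    direction = lin / spacing
    return ImageGrid(data, spacing, aff[:3, 3].copy(), direction)


def write_volume(img: ImageGrid, path, dtype=None) -> None:
    """Write as NIfTI-1 (.nii/.nii.gz) or Analyze 7.5 (.hdr/.img pair)."""
    path = str(path)
    data = img.voxels if dtype is None else np.asarray(img.voxels, dtype=dtype)
    if path.endswith((".hdr", ".img")):
        out = nib.AnalyzeImage(data, None)
        out.header.set_zooms(tuple(img.spacing))
    else:
        out = nib.Nifti1Image(data, img.affine)
        out.header.set_zooms(tuple(img.spacing))
    nib.save(out, path)
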