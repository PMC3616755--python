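"""Affine and demons-style nonrigid registration helpers.

All pipeline stages register images that already live on a common standard
grid (RAS, identity direction), so transforms are expressed in world mm and
dense displacement fields are stored voxelwise on the fixed grid.

Affine registration is 12-parameter, sum-of-squared-differences, multi-
resolution gradient descent; nonrigid refinement is an intensity-difference
driven (demons) displacement update with Gaussian field smoothing, also run
coarse-to-fine.  Both are deterministic given identical inputs.
"""

from __future__ import annotations

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from scipy.linalg import expm, logm

from .grid import ImageGrid


# -- conversions ------------------------------------------------------------

def to_sitk(img: ImageGrid) -> sitk.Image:
    # SimpleITK indexes (x, y, z); our arrays are (i, j, k) = (x, y, z).
    im = sitk.GetImageFromArray(
        np.ascontiguousarray(img.voxels.astype(np.float32).transpose(2, 1, 0)))
    im.SetSpacing(tuple(float(s) for s in img.spacing))
    im.SetOrigin(tuple(float(o) for o in img.origin))
    im.SetDirection(tuple(img.direction.flatten()))
    return im


def from_sitk(im: sitk.Image) -> ImageGrid:
    vox = sitk.GetArrayFromImage(im).transpose(2, 1, 0)
    direction = np.asarray(im.GetDirection()).reshape(3, 3)
    return ImageGrid(vox, np.asarray(im.GetSpacing()),
                     np.asarray(im.GetOrigin()), direction)


def _affine_to_matrix(tx: sitk.Transform) -> np.ndarray:
    """Homogeneous 4x4 of a sitk affine-like transform (fixed -> moving pts)."""
    tx = sitk.AffineTransform(sitk.CompositeTransform(tx).GetBackTransform()
                              if isinstance(tx, sitk.CompositeTransform) else tx)
    m = np.eye(4)
    a = np.asarray(tx.GetMatrix()).reshape(3, 3)
    c = np.asarray(tx.GetCenter())
    t = np.asarray(tx.GetTranslation())
    m[:3, :3] = a
    m[:3, 3] = t + c - a @ c
    return m


def matrix_to_affine(m: np.ndarray) -> sitk.AffineTransform:
    tx = sitk.AffineTransform(3)
    tx.SetMatrix(tuple(m[:3, :3].flatten()))
    tx.SetTranslation(tuple(m[:3, 3]))
    return tx


# -- affine -----------------------------------------------------------------

def affine_register(fixed: ImageGrid, moving: ImageGrid,
                    levels: tuple[int, ...] = (4, 2),
                    iterations: int = 80) -> np.ndarray:
    """12-parameter affine minimizing SSD; returns the 4x4 matrix mapping
    fixed-space world points to moving-space world points (the resampling
    convention: warp(moving)(x) = moving(A x))."""
    f, m = to_sitk(fixed), to_sitk(moving)
    init = sitk.CenteredTransformInitializer(
        f, m, sitk.AffineTransform(3),
        sitk.CenteredTransformInitializerFilter.GEOMETRY)

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetMetricSamplingStrategy(reg.NONE)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-4, numberOfIterations=iterations,
        relaxationFactor=0.6)
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel(list(levels))
    reg.SetSmoothingSigmasPerLevel([max(l - 1, 0) for l in levels])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    reg.SetInitialTransform(sitk.AffineTransform(init), inPlace=True)
    tx = reg.Execute(f, m)
    return _affine_to_matrix(tx)


def apply_affine(img: ImageGrid, matrix: np.ndarray, reference: ImageGrid,
                 order: int = 1, cval: float = 0.0) -> ImageGrid:
    """Resample ``img`` onto ``reference``'s grid through the world-space
    affine ``matrix`` (reference point x samples img at ``matrix @ x``)."""
    interp = sitk.sitkLinear if order == 1 else sitk.sitkNearestNeighbor
    out = sitk.Resample(to_sitk(img), to_sitk(reference),
                        matrix_to_affine(matrix), interp, float(cval))
    res = from_sitk(out)
    res.voxels = res.voxels.astype(np.float32)
    return reference.like(res.voxels)


def recenter_affines(mats: list[np.ndarray]) -> list[np.ndarray]:
    """Remove the group-average transform so the common space is unbiased.

    Subtracts the mean matrix logarithm: after recentring the average log
    transform is the identity.
    """
    logs = [np.real(logm(m)) for m in mats]
    mean_log = np.mean(logs, axis=0)
    return [np.real(expm(l - mean_log)) for l in logs]


def groupwise_affine(series: list[ImageGrid], iters: int = 2
                     ) -> tuple[list[np.ndarray], ImageGrid]:
    """Groupwise affine alignment of a series to an emergent unbiased mean.

    Iteratively registers every timepoint to the current mean, recenters the
    transforms so their average log is identity, and re-averages.  Returns
    matrices mapping each *native* image into the common space (i.e. the
    inverse of the resampling transforms) plus the final group-mean image.
    """
    if len(series) < 2:
        raise ValueError("groupwise_affine requires at least two images")
    ref = series[0]
    mean = ref.like(np.mean([s.voxels for s in series], axis=0)
                    .astype(np.float32))
    mats = [np.eye(4) for _ in series]  # fixed(common) -> moving(native)
    for _ in range(iters):
        mats = [affine_register(mean, s) for s in series]
        mats = recenter_affines(mats)
        warped = [apply_affine(s, m, ref) for s, m in zip(series, mats)]
        mean = ref.like(np.mean([w.voxels for w in warped], axis=0))
    to_common = [np.linalg.inv(m) for m in mats]
    return to_common, mean


# -- demons -----------------------------------------------------------------

def demons_register(fixed: ImageGrid, moving: ImageGrid,
                    iterations: tuple[int, ...] = (40, 30, 15),
                    smoothing_sigma: float = 2.0) -> np.ndarray:
    """Demons-style dense registration, coarse to fine.

    Returns a displacement array of shape ``fixed.shape + (3,)`` in world mm:
    the warped moving image at fixed voxel x is moving(x + d(x)).
    """
    f, m = to_sitk(fixed), to_sitk(moving)
    shrinks = [2 ** (len(iterations) - 1 - i) for i in range(len(iterations))]
    field = None
    for shrink, iters in zip(shrinks, iterations):
        fs = sitk.Shrink(f, [shrink] * 3) if shrink > 1 else f
        ms = sitk.Shrink(m, [shrink] * 3) if shrink > 1 else m
        dem = sitk.FastSymmetricForcesDemonsRegistrationFilter()
        dem.SetNumberOfIterations(int(iters))
        dem.SetSmoothDisplacementField(True)
        dem.SetStandardDeviations(smoothing_sigma)
        if field is None:
            field = dem.Execute(fs, ms)
        else:
            field = sitk.Resample(field, fs, sitk.Transform(),
                                  sitk.sitkLinear)
            field = dem.Execute(fs, ms, field)
    if field.GetSize() != f.GetSize():
        field = sitk.Resample(field, f, sitk.Transform(), sitk.sitkLinear)
    arr = sitk.GetArrayFromImage(field)  # (z, y, x, 3) with (dx, dy, dz)
    return np.ascontiguousarray(arr.transpose(2, 1, 0, 3)).astype(np.float32)


def apply_displacement(img: ImageGrid, disp_mm: np.ndarray,
                       reference: ImageGrid, order: int = 1,
                       cval: float = 0.0) -> ImageGrid:
    """Pull ``img`` onto ``reference`` through a dense mm displacement field
    defined on the reference grid (reference x samples img at x + d(x))."""
    shape = reference.shape
    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    world = (np.stack([ii, jj, kk], axis=-1) * reference.spacing
             + reference.origin + disp_mm)
    src_idx = (world - img.origin) / img.spacing
    vals = ndimage.map_coordinates(
        img.voxels.astype(np.float32), np.moveaxis(src_idx, -1, 0),
        order=order, mode="constant", cval=cval)
    return reference.like(vals.astype(img.voxels.dtype if order == 0
                                      else np.float32))


def warp_probability_map(prob: ImageGrid, target: ImageGrid,
                         template: ImageGrid | None = None,
                         demons_iterations: tuple[int, ...] = (40, 30, 15)
                         ) -> ImageGrid:
    """Warp a probability map (values in [0, 1]) onto a target image.

    The registration (affine stage, then demons refinement) is driven by the
    atlas ``template`` intensity image the map is attached to; the map itself
    is carried through the estimated transforms with linear interpolation and
    clipped back to [0, 1].  Without a template the map's own intensities
    drive the registration (adequate only when map and target are already
    intensity-comparable).
    """
    p = np.asarray(prob.voxels, dtype=np.float32)
    if p.min() < -1e-6 or p.max() > 1 + 1e-6:
        raise ValueError("probability map values must lie in [0, 1]")
    driver = template if template is not None else prob
    _, out = warp_map_pair(driver, prob, target,
                           demons_iterations=demons_iterations)
    out.voxels = np.clip(out.voxels, 0.0, 1.0)
    return out


def warp_map_pair(template: ImageGrid, extra: ImageGrid, target: ImageGrid,
                  order: int = 1,
                  demons_iterations: tuple[int, ...] = (40, 30, 15)
                  ) -> tuple[ImageGrid, ImageGrid]:
    """Register ``template`` to ``target`` (affine + demons) and carry the
    companion volume ``extra`` (e.g. an atlas mask or prior defined on the
    template grid) through the same transforms."""
    mat = affine_register(target, template)
    t_aff = apply_affine(template, mat, target)
    disp = demons_register(target, t_aff, iterations=demons_iterations)
    t_out = apply_displacement(t_aff, disp, target)
    e_aff = apply_affine(extra, mat, target, order=order)
    e_out = apply_displacement(e_aff, disp, target, order=order)
    return t_out, e_out
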