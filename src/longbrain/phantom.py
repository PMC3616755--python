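"""Synthetic longitudinal head-MRI phantoms with full ground truth.

The generator emits a serial T1-like study of one "subject": concentric,
slightly ellipsoidal compartments (scalp, skull, CSF, cortical GM shell, WM
core) plus a cerebellum-like blob, degraded per timepoint by GM atrophy
(linear outer-shell thinning), a smooth multiplicative bias field, additive
Gaussian noise and a small rigid misalignment.  Alongside the images it
returns every ground-truth object the pipeline stages are scored against
(brain/cerebellum masks, tissue labels, ROI labels, thickness, bias fields,
rigid transforms) and a matching synthetic atlas (noise-free baseline
anatomy with a brain-probability map, tissue priors, angular-sector ROI
parcellation and cerebellum mask).

A fixed smooth "texture" modulation of the tissue intensities — part of the
anatomy, identical at every timepoint — gives the otherwise radially
symmetric phantom distinctive features, without which feature-based
registration would be ill-posed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .grid import ImageGrid

BACKGROUND, CSF, GM, WM = 0, 1, 2, 3


@dataclass
class PhantomSpec:
    """Study conditions for one synthetic longitudinal series.

    Radii are in mm and must decrease strictly from scalp to WM; the default
    schedule (baseline, 6, 12, 24 months) and the 96-cubed 1 mm grid are the
    phantom-scale test profile.  ``gm_thinning_rate`` shrinks the outer GM
    radius, i.e. cortical thickness declines by rate x month.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    timepoints: tuple[float, ...] = (0.0, 6.0, 12.0, 24.0)
    radius_scalp: float = 44.0
    radius_skull: float = 40.0
    radius_csf: float = 36.0       # outer brain boundary
    radius_gm: float = 33.0        # outer cortical surface at baseline
    radius_wm: float = 30.0
    gm_thinning_rate: float = 0.025     # mm per month
    intensities: dict = field(default_factory=lambda: {
        "background": 0.0, "csf": 40.0, "gm": 80.0, "wm": 120.0,
        "skull": 20.0, "scalp": 90.0})
    noise_sigma: float = 4.0
    bias_amplitude: float = 0.15
    bias_frequency: float = 0.7    # cycles across the field of view
    jitter_translation: float = 2.0   # max |mm| per axis, t > 0
    jitter_rotation: float = 2.0      # max |deg| per axis, t > 0
    cerebellum_center: tuple[float, float, float] = (0.0, -14.0, -18.0)
    cerebellum_radius: float = 9.0
    ellipsoid_scale: tuple[float, float, float] = (1.0, 1.12, 0.94)
    texture_amplitude: float = 0.08
    texture_sigma: float = 4.0     # mm correlation length of the texture
    pv_smoothing_mm: float = 0.6   # partial-volume blur; 0 = crisp classes
    n_rois: int = 10               # per hemisphere
    seed: int = 0

    def validate(self) -> None:
        radii = [self.radius_scalp, self.radius_skull, self.radius_csf,
                 self.radius_gm, self.radius_wm]
        if not all(a > b for a, b in zip(radii, radii[1:])):
            raise ValueError("radii must decrease strictly scalp -> wm")
        months = max(self.timepoints)
        thickness = (self.radius_gm - self.gm_thinning_rate * months
                     - self.radius_wm)
        if not 0.5 < thickness < 8.0 or not 0.5 < self.radius_gm - self.radius_wm < 8.0:
            raise ValueError("GM thickness leaves (0.5, 8) mm over the study")


@dataclass
class PhantomTruth:
    """Ground truth emitted alongside a synthetic series (one entry per
    timepoint unless noted)."""

    brain_masks: list[np.ndarray]
    cerebellum_masks: list[np.ndarray]
    tissue_labels: list[np.ndarray]        # 0 bg, 1 CSF, 2 GM, 3 WM
    roi_labels: list[np.ndarray]
    thickness: list[float]                 # true GM shell thickness, mm
    bias_fields: list[np.ndarray]
    rigid_transforms: list[np.ndarray]     # 4x4 world maps, native -> anatomy


@dataclass
class SyntheticAtlas:
    """Noise-free baseline anatomy standing in for a labelled atlas."""

    template: ImageGrid
    brain_probability: ImageGrid
    tissue_priors: dict                    # {"csf": ImageGrid, ...}
    labels: ImageGrid
    cerebellum_mask: ImageGrid


def _world_coords(spec: PhantomSpec) -> np.ndarray:
    shape = np.asarray(spec.shape)
    spacing = np.asarray(spec.spacing)
    origin = -spacing * (shape - 1) / 2.0
    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    return np.stack([ii, jj, kk], axis=-1) * spacing + origin, origin


def _radial(world: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Elliptical radius field: r(x) = ||x / scale||."""
    scale = np.asarray(spec.ellipsoid_scale)
    return np.linalg.norm(world / scale, axis=-1)


def _anatomy(spec: PhantomSpec, r: np.ndarray, cereb_blob: np.ndarray,
             gm_radius: float):
    """Tissue labels, head labels (incl. skull/scalp), cerebellum blob and
    brain mask for a given outer-GM radius (thinning enters through
    ``gm_radius``)."""
    head = np.zeros(r.shape, dtype=np.uint8)  # 0 bg,1 csf,2 gm,3 wm,4 skull,5 scalp
    head[r < spec.radius_scalp] = 5
    head[r < spec.radius_skull] = 4
    head[r < spec.radius_csf] = 1
    head[r < gm_radius] = 2
    head[r < spec.radius_wm] = 3
    brain = (head >= 1) & (head <= 3)
    # cerebellum blob: GM-intensity tissue inside the brain, tracked apart
    cereb = cereb_blob & brain
    tissue = np.where(head <= 3, head, 0).astype(np.uint8)
    tissue[cereb & (tissue == CSF)] = GM
    return tissue, head, cereb, brain


def _intensity_volume(spec: PhantomSpec, tissue, head, texture) -> np.ndarray:
    inten = spec.intensities
    lut = {0: inten["background"], 1: inten["csf"], 2: inten["gm"],
           3: inten["wm"], 4: inten["skull"], 5: inten["scalp"]}
    vol = np.zeros(head.shape, dtype=np.float32)
    for lab, val in lut.items():
        vol[head == lab] = val
    vol[tissue == GM] = inten["gm"]
    vol *= (1.0 + texture)
    if spec.pv_smoothing_mm <= 0:
        return vol
    # mild partial-volume smoothing
    return ndimage.gaussian_filter(
        vol, sigma=spec.pv_smoothing_mm / np.min(spec.spacing))


def _rigid_matrix(rng: np.random.Generator, spec: PhantomSpec) -> np.ndarray:
    t = rng.uniform(-spec.jitter_translation, spec.jitter_translation, 3)
    angles = rng.uniform(-spec.jitter_rotation, spec.jitter_rotation, 3)
    m = np.eye(4)
    m[:3, :3] = Rotation.from_euler("xyz", angles, degrees=True).as_matrix()
    m[:3, 3] = t
    return m


def _resample_world(vol: np.ndarray, matrix: np.ndarray, spacing, origin,
                    order: int) -> np.ndarray:
    """Sample ``vol`` at matrix @ x for every output world point x."""
    if np.allclose(matrix, np.eye(4), atol=1e-12):
        return np.asarray(vol, dtype=np.float32).copy()
    shape = vol.shape
    grids = np.meshgrid(*[np.arange(n, dtype=np.float32) for n in shape],
                        indexing="ij")
    world = np.stack([g.ravel() for g in grids], axis=1)
    world *= np.asarray(spacing, dtype=np.float32)
    world += np.asarray(origin, dtype=np.float32)
    src = world @ matrix[:3, :3].T.astype(np.float32) \
        + matrix[:3, 3].astype(np.float32)
    idx = (src - origin) / np.asarray(spacing)
    return ndimage.map_coordinates(
        np.asarray(vol, dtype=np.float32), idx.T.reshape(3, *shape),
        order=order, mode="constant", cval=0.0)


def generate_phantom(spec: PhantomSpec
                     ) -> tuple[list[ImageGrid], PhantomTruth, SyntheticAtlas]:
    """Generate the longitudinal series, its ground truth and the atlas.

    Fully reproducible from ``spec.seed``: the anatomy texture, the bias
    field phase, noise and rigid jitter all derive from it.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    world, origin = _world_coords(spec)
    spacing = np.asarray(spec.spacing)
    r = _radial(world, spec)
    diff = (world - np.asarray(spec.cerebellum_center)).astype(np.float32)
    cereb_blob = np.einsum("...i,...i->...", diff, diff) \
        < spec.cerebellum_radius ** 2

    # anatomy-fixed texture (same realization at every timepoint)
    tex = rng.standard_normal(spec.shape)
    tex = ndimage.gaussian_filter(tex, spec.texture_sigma / np.min(spacing))
    tex *= spec.texture_amplitude / max(tex.std(), 1e-12)

    # smooth multiplicative bias: 1 + A sin(fx) sin(fy) sin(fz), scanner-fixed
    fov = np.asarray(spec.shape) * spacing
    phase = rng.uniform(0, 2 * np.pi, 3)
    sines = [np.sin(2 * np.pi * spec.bias_frequency * world[..., a] / fov[a]
                    + phase[a]) for a in range(3)]
    bias = 1.0 + spec.bias_amplitude * sines[0] * sines[1] * sines[2]

    # ROI parcellation on the baseline brain (excluding the cerebellum blob):
    # hemispheres split by x sign, angular sectors of atan2(z, y) within each.
    tissue0, head0, cereb0, brain0 = _anatomy(spec, r, cereb_blob, spec.radius_gm)
    ang = np.arctan2(world[..., 2], world[..., 1])  # (-pi, pi]
    sector = np.minimum((ang + np.pi) / (2 * np.pi) * spec.n_rois,
                        spec.n_rois - 1e-9).astype(int)
    hemi = (world[..., 0] >= 0).astype(int)
    roi0 = np.where(brain0 & ~cereb0,
                    1 + sector + hemi * spec.n_rois, 0).astype(np.int16)

    series, truth = [], PhantomTruth([], [], [], [], [], [], [])
    for ti, month in enumerate(spec.timepoints):
        gm_radius = spec.radius_gm - spec.gm_thinning_rate * month
        tissue, head, cereb, brain = _anatomy(spec, r, cereb_blob, gm_radius)
        clean = _intensity_volume(spec, tissue, head, tex)

        if ti == 0:
            rigid = np.eye(4)
        else:
            rigid = _rigid_matrix(rng, spec)
        moved = _resample_world(clean, rigid, spacing, origin, order=1)
        noisy = moved * bias + rng.normal(0.0, spec.noise_sigma, spec.shape)
        img = ImageGrid(np.maximum(noisy, 0.0).astype(np.float32),
                        spacing.copy(), origin.copy(), np.eye(3))
        series.append(img)

        def _move_mask(m):
            return _resample_world(m.astype(np.float32), rigid, spacing,
                                   origin, order=1) > 0.5

        truth.brain_masks.append(_move_mask(brain))
        truth.cerebellum_masks.append(_move_mask(cereb))
        lab = _resample_world(tissue.astype(np.float32), rigid, spacing,
                              origin, order=0).astype(np.uint8)
        truth.tissue_labels.append(lab)
        roi = _resample_world(roi0.astype(np.float32), rigid, spacing,
                              origin, order=0).astype(np.int16)
        roi[lab == 0] = 0
        truth.roi_labels.append(roi)
        truth.thickness.append(gm_radius - spec.radius_wm)
        truth.bias_fields.append(bias.copy())
        truth.rigid_transforms.append(rigid)

    # atlas: clean, unjittered baseline anatomy
    def _grid(v, dtype=np.float32):
        return ImageGrid(np.asarray(v, dtype=dtype), spacing.copy(),
                         origin.copy(), np.eye(3))

    smooth = 2.0 / np.min(spacing)
    prob = np.clip(ndimage.gaussian_filter(brain0.astype(np.float32), smooth),
                   0.0, 1.0)
    priors = {}
    for name, lab in (("csf", CSF), ("gm", GM), ("wm", WM)):
        priors[name] = _grid(np.clip(ndimage.gaussian_filter(
            (tissue0 == lab).astype(np.float32), smooth), 0.0, 1.0))
    atlas = SyntheticAtlas(
        template=_grid(_intensity_volume(spec, tissue0, head0, tex)),
        brain_probability=_grid(prob),
        tissue_priors=priors,
        labels=_grid(roi0, dtype=np.int16),
        cerebellum_mask=_grid(cereb0.astype(np.uint8), dtype=np.uint8),
    )
    return series, truth, atlas
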