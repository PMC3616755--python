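"""Joint WM/GM/CSF segmentation with coupled level sets and thickness
constraints.

Three signed functions per timepoint carry the WM/GM, GM/CSF and
CSF/background interfaces (negative inside, mm units, signed-distance in the
narrow band).  The evolution combines

* a data-fitting term: the difference of local Gaussian log-likelihoods of
  the two tissues adjoining each interface, with spatially varying means and
  variances estimated inside Gaussian windows;
* a spatial cortical-thickness constraint penalizing thickness outside the
  biologically plausible 1-6.5 mm band;
* a temporal thickness-consistency term (4D runs) that drives the current
  thickness toward the interval spanned by its immediate temporal
  neighbours, whose thickness maps are pulled into the current frame by a
  demons-style registration of the tissue maps.

The outer loop alternates inter-timepoint registration with constrained
evolution until labels stabilize; a single timepoint runs the 3D path only.
The CSF/background interface is pinned to the brain-extraction mask, so the
three tissue labels always partition the brain mask exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import ImageGrid
from .registration import demons_register

BACKGROUND, CSF, GM, WM = 0, 1, 2, 3
_CLASSES = {"csf": CSF, "gm": GM, "wm": WM}


# ---------------------------------------------------------------------------
# state containers


@dataclass
class LevelSetState:
    """Signed interface functions for one timepoint (negative inside)."""

    phi_wm: np.ndarray     # zero level = WM/GM interface
    phi_gm: np.ndarray     # zero level = GM/CSF interface ({phi<0} = WM+GM)
    phi_csf: np.ndarray    # zero level = CSF/background ({phi<0} = brain)
    geometry: ImageGrid

    def labels(self) -> np.ndarray:
        lab = np.zeros(self.phi_wm.shape, dtype=np.uint8)
        brain = self.phi_csf < 0
        lab[brain] = CSF
        lab[brain & (self.phi_gm < 0)] = GM
        lab[brain & (self.phi_wm < 0)] = WM
        return lab

    def nesting_ok(self) -> bool:
        return bool(np.all(self.phi_wm >= self.phi_gm - 1e-6)
                    and np.all(self.phi_gm >= self.phi_csf - 1e-6))


@dataclass
class LocalStats:
    """Spatially varying Gaussian intensity model per tissue class."""

    mean: dict
    variance: dict
    window_fwhm: float


@dataclass
class ThicknessMap:
    """Cortical thickness (mm) on GM voxels: |phi_wm| + |phi_gm|."""

    thickness: np.ndarray
    gm_mask: np.ndarray

    def mean(self) -> float:
        if not self.gm_mask.any():
            return float("nan")
        return float(self.thickness[self.gm_mask].mean())


@dataclass
class SegWeights:
    """Weights and schedule of the segmentation evolution."""

    lambda_data: float = 1.0
    lambda_spatial_thick: float = 0.5
    lambda_temporal_thick: float = 0.5
    mu_smooth: float = 0.2
    dt: float = 0.4
    t_min: float = 1.0
    t_max: float = 6.5
    iters: int = 60
    reinit_every: int = 20
    thickness_every: int = 5   # cadence of thickness-field recomputation
    curvature_every: int = 3   # cadence of curvature recomputation
    delta_eps: float = 1.5     # mm width of the smoothed interface delta

    def __post_init__(self) -> None:
        if self.t_min >= self.t_max:
            raise ValueError("t_min must be below t_max")


# ---------------------------------------------------------------------------
# helpers


def _signed_distance(region: np.ndarray, spacing) -> np.ndarray:
    """Signed Euclidean distance in mm, negative inside ``region``.

    Voxel-center distances are shifted by half a voxel toward the interface
    (the boundary lies on the face between an inside and an outside voxel),
    which makes |phi| the distance to the interface itself; without the
    shift a slab of n voxels would measure (n + 1) voxels thick.
    """
    region = np.asarray(region) > 0
    if not region.any():
        return np.full(region.shape, 1e3, dtype=np.float32)
    if region.all():
        return np.full(region.shape, -1e3, dtype=np.float32)
    h = 0.5 * float(np.mean(spacing))
    outside = ndimage.distance_transform_edt(~region, sampling=spacing)
    inside = ndimage.distance_transform_edt(region, sampling=spacing)
    phi = np.where(region, -(inside - h), outside - h)
    return phi.astype(np.float32)


def _project_nesting(state: LevelSetState) -> None:
    np.maximum(state.phi_gm, state.phi_csf, out=state.phi_gm)
    np.maximum(state.phi_wm, state.phi_gm, out=state.phi_wm)


def _fit_gmm_1d(values: np.ndarray, n_iter: int = 30):
    """Deterministic 3-class 1-D EM, means initialized evenly across the
    robust intensity range.  Returns (means, variances, weights) sorted by
    mean, or None on degeneracy."""
    v = np.asarray(values, dtype=np.float64)
    lo, hi = np.percentile(v, [1, 99])
    if hi - lo < 1e-9:
        return None
    mu = lo + (hi - lo) * np.array([0.25, 0.5, 0.75])
    var = np.full(3, max(v.var() / 9.0, 1e-6))
    pi = np.full(3, 1 / 3)
    for _ in range(n_iter):
        logp = (-0.5 * (v[:, None] - mu) ** 2 / var
                - 0.5 * np.log(2 * np.pi * var) + np.log(pi))
        logp -= logp.max(axis=1, keepdims=True)
        r = np.exp(logp)
        r /= r.sum(axis=1, keepdims=True)
        nk = r.sum(axis=0)
        if np.any(nk < 10):
            return None
        mu = (r * v[:, None]).sum(axis=0) / nk
        var = (r * (v[:, None] - mu) ** 2).sum(axis=0) / nk
        var = np.maximum(var, 1e-6)
        pi = nk / len(v)
    order = np.argsort(mu)
    return mu[order], var[order], pi[order]


# ---------------------------------------------------------------------------
# public operations


def init_levelsets(brain: ImageGrid, priors: dict) -> LevelSetState:
    """Initialize the three interfaces from atlas priors and global EM.

    Voxel posteriors are proportional to atlas prior times a global 3-class
    Gaussian likelihood fitted by EM on the masked intensities (CSF, GM, WM
    ordered by increasing mean, the T1 convention).  Hard max-posterior
    labels are nested by construction and converted to signed distances.
    A degenerate EM falls back to a quantile-based 3-way split.
    """
    vox = np.asarray(brain.voxels, dtype=np.float64)
    mask = vox > 0
    vals = vox[mask]
    fit = _fit_gmm_1d(vals)
    if fit is None:
        # quantile-based 3-way split: means at the tercile centers
        mu = np.quantile(vals, [1 / 6, 3 / 6, 5 / 6])
        mu = np.maximum.accumulate(mu + np.arange(3) * 1e-6)
        var = np.full(3, max(vals.var() / 9.0, 1e-6))
    else:
        mu, var, _ = fit

    eps = 1e-3
    post = np.zeros((3,) + vox.shape)
    for k, name in enumerate(("csf", "gm", "wm")):
        pr = np.asarray(priors[name].voxels, dtype=np.float64)
        loglike = (-0.5 * (vox - mu[k]) ** 2 / var[k]
                   - 0.5 * np.log(2 * np.pi * var[k]))
        post[k] = np.log(pr + eps) + loglike
    hard = np.argmax(post, axis=0) + 1   # 1 CSF, 2 GM, 3 WM
    hard[~mask] = 0

    wm_region = hard == WM
    gm_region = hard >= GM               # WM + GM, nesting by construction
    spacing = brain.spacing
    return LevelSetState(
        phi_wm=_signed_distance(wm_region, spacing),
        phi_gm=_signed_distance(gm_region, spacing),
        phi_csf=_signed_distance(mask, spacing),
        geometry=brain,
    )


def fit_local_stats(brain: ImageGrid, state: LevelSetState,
                    window_fwhm: float = 15.0,
                    variance_floor: float = 1.0) -> LocalStats:
    """Spatially varying mean/variance per class via smoothed-indicator
    ratios: Gaussian windows of the given FWHM centered at every voxel."""
    if not state.nesting_ok():
        raise ValueError("level-set nesting is violated")
    vox = np.asarray(brain.voxels, dtype=np.float64)
    labels = state.labels()
    sigma = window_fwhm / 2.3548 / np.asarray(brain.spacing)
    means, variances = {}, {}
    for name, lab in _CLASSES.items():
        chi = (labels == lab).astype(np.float64)
        if chi.sum() == 0:
            continue  # class dropped; caller keeps previous stats
        den = ndimage.gaussian_filter(chi, sigma)
        num = ndimage.gaussian_filter(chi * vox, sigma)
        num2 = ndimage.gaussian_filter(chi * vox ** 2, sigma)
        g_mean = vox[labels == lab].mean()
        g_var = max(vox[labels == lab].var(), variance_floor)
        ok = den > 1e-6
        m = np.where(ok, num / np.maximum(den, 1e-12), g_mean)
        v = np.where(ok, num2 / np.maximum(den, 1e-12) - m ** 2, g_var)
        means[name] = m
        variances[name] = np.maximum(v, variance_floor)
    return LocalStats(means, variances, window_fwhm)


def estimate_thickness(state: LevelSetState) -> ThicknessMap:
    """Cortical thickness at each GM voxel: distance to the WM/GM surface
    plus distance to the GM/CSF surface, |phi_wm| + |phi_gm|."""
    gm = (state.phi_wm >= 0) & (state.phi_gm < 0) & (state.phi_csf < 0)
    thick = np.zeros(state.phi_wm.shape, dtype=np.float32)
    thick[gm] = (np.abs(state.phi_wm[gm]) + np.abs(state.phi_gm[gm]))
    return ThicknessMap(thick, gm)


def _extend_to_band(values: np.ndarray, support: np.ndarray) -> np.ndarray:
    """Extend a field defined on ``support`` to all voxels by nearest
    support voxel (used to evaluate GM thickness near the interfaces)."""
    if not support.any():
        return np.zeros_like(values)
    _, inds = ndimage.distance_transform_edt(~support, return_indices=True)
    return values[tuple(inds)]


def _delta(phi: np.ndarray, eps: float) -> np.ndarray:
    return eps / (np.pi * (eps ** 2 + phi ** 2))


def _curvature(phi: np.ndarray, spacing) -> np.ndarray:
    g = np.gradient(phi, *spacing)
    norm = np.sqrt(g[0] ** 2 + g[1] ** 2 + g[2] ** 2) + 1e-8
    k = sum(np.gradient(g[a] / norm, spacing[a], axis=a) for a in range(3))
    return np.clip(k, -1.0, 1.0)


def _loglike(vox, stats: LocalStats, name: str) -> np.ndarray:
    m, v = stats.mean[name], stats.variance[name]
    return -0.5 * (vox - m) ** 2 / v - 0.5 * np.log(v)


def compute_energy(brain: ImageGrid, state: LevelSetState,
                   stats: LocalStats, w: SegWeights) -> float:
    """Total energy: negative local log-likelihood of the labeling, interface
    area weighted by ``mu_smooth``, and the quadratic thickness penalties."""
    vox = np.asarray(brain.voxels, dtype=np.float64)
    labels = state.labels()
    e_data = 0.0
    for name, lab in _CLASSES.items():
        sel = labels == lab
        e_data -= _loglike(vox, stats, name)[sel].sum()
    e_area = 0.0
    for phi in (state.phi_wm, state.phi_gm):
        d = _delta(phi, w.delta_eps)
        g = np.gradient(phi, *state.geometry.spacing)
        e_area += (d * np.sqrt(g[0] ** 2 + g[1] ** 2 + g[2] ** 2)).sum()
    tm = estimate_thickness(state)
    t = tm.thickness[tm.gm_mask]
    e_pen = (np.maximum(w.t_min - t, 0) ** 2).sum() \
        + (np.maximum(t - w.t_max, 0) ** 2).sum()
    return float(w.lambda_data * e_data + w.mu_smooth * e_area
                 + w.lambda_spatial_thick * e_pen)


def evolve_segmentation(brain: ImageGrid, state: LevelSetState,
                        stats: LocalStats,
                        neighbor_thickness: tuple | None = None,
                        w: SegWeights | None = None,
                        iters: int | None = None) -> LevelSetState:
    """Gradient-flow evolution of the WM/GM and GM/CSF interfaces.

    ``neighbor_thickness`` is a pair of :class:`ThicknessMap` (or a 1-tuple
    at series endpoints) already resampled into this timepoint's frame; when
    given, the temporal term penalizes thickness outside the interval spanned
    by the neighbours.  The CSF/background interface stays pinned to the
    brain mask; nesting is re-enforced after every update and the signed
    functions are re-initialized every ``reinit_every`` iterations.
    """
    w = w or SegWeights()
    n_it = int(iters if iters is not None else w.iters)
    vox = np.asarray(brain.voxels, dtype=np.float64)
    spacing = state.geometry.spacing
    mask = vox > 0

    phi_wm = state.phi_wm.astype(np.float32).copy()
    phi_gm = state.phi_gm.astype(np.float32).copy()
    phi_csf = state.phi_csf.astype(np.float32).copy()

    ll = {name: _loglike(vox, stats, name) for name in stats.mean}
    # >0 favors the outer class of each interface
    f_wm = np.clip(ll["gm"] - ll["wm"], -2.0, 2.0).astype(np.float32)
    f_gm = np.clip(ll["csf"] - ll["gm"], -2.0, 2.0).astype(np.float32)

    nb_lo = nb_hi = None
    if neighbor_thickness:
        fields = [_extend_to_band(t.thickness, t.gm_mask)
                  for t in neighbor_thickness]
        nb_lo = np.minimum.reduce(fields)
        nb_hi = np.maximum.reduce(fields)

    cur = LevelSetState(phi_wm, phi_gm, phi_csf, state.geometry)
    t_ext = curv_wm = curv_gm = None
    for it in range(n_it):
        if t_ext is None or it % max(w.thickness_every, 1) == 0:
            tm = estimate_thickness(cur)
            t_ext = _extend_to_band(tm.thickness, tm.gm_mask)
        if curv_wm is None or it % max(w.curvature_every, 1) == 0:
            curv_wm = _curvature(phi_wm, spacing)
            curv_gm = _curvature(phi_gm, spacing)

        s_pen = (np.maximum(w.t_min - t_ext, 0.0)
                 - np.maximum(t_ext - w.t_max, 0.0))
        upd_wm = w.lambda_data * f_wm + w.lambda_spatial_thick * s_pen
        upd_gm = w.lambda_data * f_gm - w.lambda_spatial_thick * s_pen
        if nb_lo is not None:
            dtt = t_ext - np.clip(t_ext, nb_lo, nb_hi)
            upd_wm -= w.lambda_temporal_thick * dtt
            upd_gm += w.lambda_temporal_thick * dtt

        phi_wm += (w.dt * _delta(phi_wm, w.delta_eps)
                   * (upd_wm + w.mu_smooth * curv_wm)).astype(np.float32)
        phi_gm += (w.dt * _delta(phi_gm, w.delta_eps)
                   * (upd_gm + w.mu_smooth * curv_gm)).astype(np.float32)
        _project_nesting(cur)

        if (it + 1) % w.reinit_every == 0 and it + 1 < n_it:
            phi_wm[:] = _signed_distance(phi_wm < 0, spacing)
            phi_gm[:] = _signed_distance((phi_gm < 0) & mask, spacing)
            _project_nesting(cur)

    phi_wm[:] = _signed_distance(phi_wm < 0, spacing)
    phi_gm[:] = _signed_distance((phi_gm < 0) & mask, spacing)
    _project_nesting(cur)
    out = LevelSetState(phi_wm.astype(np.float32), phi_gm.astype(np.float32),
                        phi_csf.astype(np.float32), state.geometry)
    return out


def register_tissue_maps(seg_t: np.ndarray, seg_t1: np.ndarray,
                         geometry: ImageGrid,
                         iterations: tuple[int, ...] = (30, 20, 10)
                         ) -> np.ndarray:
    """Demons-style registration of smoothed label images.

    Returns a displacement field (mm, on ``geometry``) mapping timepoint-t
    coordinates into timepoint t+1: neighbour maps are pulled into the
    current frame by sampling at x + d(x).
    """
    sm = 1.0 / np.min(geometry.spacing)
    a = ndimage.gaussian_filter(np.asarray(seg_t, dtype=np.float32), sm)
    b = ndimage.gaussian_filter(np.asarray(seg_t1, dtype=np.float32), sm)
    return demons_register(geometry.like(a), geometry.like(b),
                           iterations=iterations)


def _pull_thickness(tm: ThicknessMap, disp_mm: np.ndarray,
                    geometry: ImageGrid) -> ThicknessMap:
    shape = geometry.shape
    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    world = (np.stack([ii, jj, kk], axis=-1) * geometry.spacing
             + geometry.origin + disp_mm)
    idx = np.moveaxis((world - geometry.origin) / geometry.spacing, -1, 0)
    ext = _extend_to_band(tm.thickness, tm.gm_mask)
    thick = ndimage.map_coordinates(ext, idx, order=1, mode="nearest")
    msk = ndimage.map_coordinates(tm.gm_mask.astype(np.float32), idx,
                                  order=1, mode="constant") > 0.25
    return ThicknessMap(thick.astype(np.float32), msk)


def segment_series_4d(series: list[ImageGrid], priors,
                      w: SegWeights | None = None, outer_iters: int = 3,
                      window_fwhm: float = 15.0,
                      label_change_tol: float = 1e-3
                      ) -> tuple[list[ImageGrid], list[ThicknessMap]]:
    """Alternating 4D segmentation of a brain-extracted series.

    Step 1: independent 3D coupled-level-set segmentation per timepoint
    (data + spatial thickness constraint).  Then, repeatedly: register the
    current tissue maps of temporal neighbours into each frame, and re-run
    the evolution with the temporal thickness-consistency term; stop when
    fewer than ``label_change_tol`` of voxels change label or after
    ``outer_iters`` rounds.  A single timepoint runs only the 3D path.

    ``priors`` is either one dict of CSF/GM/WM probability grids applied to
    every timepoint or a list of such dicts.
    """
    w = w or SegWeights()
    nt = len(series)
    if nt == 0:
        raise ValueError("empty series")
    prior_list = priors if isinstance(priors, list) else [priors] * nt

    states, stats = [], []
    for img, pr in zip(series, prior_list):
        st = init_levelsets(img, pr)
        lo = fit_local_stats(img, st, window_fwhm)
        st = evolve_segmentation(img, st, lo, None, w)
        states.append(st)
        stats.append(fit_local_stats(img, st, window_fwhm))

    if nt > 1:
        prev_labels = [s.labels() for s in states]
        for _ in range(int(outer_iters)):
            thicks = [estimate_thickness(s) for s in states]
            labels = [s.labels() for s in states]
            new_states = []
            for t in range(nt):
                # immediate temporal neighbours; endpoints use their single
                # neighbour (the clamp interval then degenerates to it)
                nbrs = []
                for j in (t - 1, t + 1):
                    if 0 <= j < nt:
                        d = register_tissue_maps(labels[t], labels[j],
                                                 series[t])
                        nbrs.append(_pull_thickness(thicks[j], d,
                                                    series[t]))
                st = evolve_segmentation(series[t], states[t], stats[t],
                                         tuple(nbrs), w)
                new_states.append(st)
            states = new_states
            stats = [fit_local_stats(series[t], states[t], window_fwhm)
                     for t in range(nt)]
            cur_labels = [s.labels() for s in states]
            changed = sum((a != b).sum() for a, b in
                          zip(prev_labels, cur_labels))
            total = sum(a.size for a in cur_labels)
            prev_labels = cur_labels
            if changed / total < label_change_tol:
                break

    label_grids = [img.like(s.labels())
                   for img, s in zip(series, states)]
    thickness = [estimate_thickness(s) for s in states]
    return label_grids, thickness
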