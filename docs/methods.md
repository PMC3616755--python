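# Methods

`longbrain` analyses serial T1-weighted MR images of one adult subject
*jointly* across timepoints.  The premise throughout is that a subject's
anatomy changes slowly and smoothly, so independent per-image processing —
which lets segmentation noise masquerade as longitudinal change — is
replaced at every stage by a coupled 4D formulation.  This note records the
models, the concrete numerical choices, and what the synthetic studies do
and do not establish.

## Geometry and I/O

Volumes are `ImageGrid` objects: a 3-D array plus spacing (mm), origin and
an orthonormal direction matrix mapping voxel axes into world RAS
coordinates, with the voxel-center convention
`world = direction · diag(spacing) · index + origin`.  Inputs in any
orientation are reoriented by one of the 24 right-handed axis
relabellings (enumerable; chosen automatically from NIfTI metadata or
passed explicitly — Analyze 7.5 files carry no orientation and are flagged
accordingly) and resampled trilinearly onto a configurable standard grid.
The standard profile is 1 mm isotropic on 256³; every phantom experiment
uses the same spacing on 96³ or smaller, which keeps the studies faithful
in resolution while fitting a single CPU.

## Preprocessing

**Bias correction** is a compact re-implementation of the N3 idea: in the
log-intensity domain, iterate (a) sharpening of the masked intensity
histogram against a Gaussian blur kernel (Wiener deconvolution, 200 bins,
FWHM 0.15 log units) giving a per-voxel expectation of the unbiased
intensity, and (b) a smooth-field fit of the residual — least-squares
block means on a control lattice (default 40 mm knots) upsampled with
cubic splines.  The accumulated log-field is normalized to zero mean over
the mask, so the masked mean intensity is preserved to well under 1%.  It
is *not* byte-compatible with the MINC tool; on phantoms with a known
smooth multiplicative field the recovered gain correlates with truth above
0.95 when the knot spacing resolves the field.  The knot spacing is the
parameter that matters: a field with structure finer than the lattice
cannot be captured (deliberately — that protects anatomy from being
"corrected" away).

**Histogram matching** maps each follow-up onto the baseline through a
monotone piecewise-linear map of 128 matched quantiles, with the end
segments extended linearly (no flat tails, so matching an image to itself
is the exact identity).  Matching uses the positive support of each image
by default, or brain-probability-weighted masks when available; follow-ups
are matched to baseline only (star topology, no chaining).

## 4D brain extraction

One closed triangle mesh per timepoint — a subdivided icosahedron, all
timepoints sharing the identical triangle array — is evolved
simultaneously.  Initialization: groupwise affine alignment of the series
to an unbiased common space (per-round recentring so the average matrix
logarithm of the transforms is identity), warping of the atlas brain
probability map onto each aligned image (affine + demons, driven by the
atlas template), probability stripping at P ≥ 0.5, one sphere per
timepoint (intensity-weighted centroid; equivalent-volume radius), and a
common averaged sphere imposed on every timepoint.

Per iteration each vertex moves by `step_size` times the sum of
* a smoothness force toward the one-ring centroid, tangential part fully
  applied, normal part attenuated by a curvature sigmoid (radii 3.33–10 mm,
  the classic surface-stripping construction);
* an intensity force along the normal comparing the minimum intensity
  within 7 mm inward and the maximum within 3 mm against adaptive
  thresholds (2nd/98th percentiles, fractional threshold 0.5);
* a probability force along the normal proportional to P − ½;
* a temporal force toward the mean position of the same vertex at the
  immediate temporal neighbours, evaluated on the pre-iteration state
  (Jacobi style), so a time-symmetric series evolves symmetrically.

Defaults: weights (1.0, 0.3, 0.3, 0.5), step 0.1 mm, 1000 iterations
(evaluation studies use 300, which suffices when the initial sphere comes
from the probability-stripped volume).  With the temporal weight at zero
the scheme is, bit for bit, the independent per-timepoint 3D evolution —
this reduction is asserted in the tests.  Masks are rasterized from the
final surfaces by z-column ray parity at voxel centers (volumes within 2%
of analytic spheres), and the cerebellum is removed by registering the
atlas (affine + demons) to the groupwise mean of the brain-extracted
images and carrying its cerebellum mask into each native frame.
Self-intersection is screened with a broad-phase triangle test and only
warned about: the smoothing force empirically prevents folding.

## 4D tissue segmentation

Three signed functions per timepoint carry the WM/GM, GM/CSF and
CSF/background interfaces (negative inside; signed Euclidean distance with
a half-voxel correction so that a slab of n voxels measures n mm thick,
not n+1).  The CSF/background function stays pinned to the skull-stripping
mask — the outer boundary was already decided by extraction — which makes
the three labels partition the brain mask exactly at every iteration.

The evolution combines, per interface,
* a data term: difference of local Gaussian log-likelihoods of the two
  adjoining tissues, with spatially varying means/variances estimated by
  Gaussian-window smoothed-indicator ratios (FWHM 15 mm, variance floored
  at 1 intensity-unit²), clipped to ±2 for stability;
* curvature regularization (weight 0.2);
* a spatial thickness constraint: cortical thickness T = |φ_wm| + |φ_gm|
  on GM voxels, extended to the interface band by nearest-GM lookup, with
  a linear penalty outside the biologically plausible 1–6.5 mm band
  driving both interfaces in the thickness-restoring direction;
* a temporal consistency term (4D runs): T is penalized in proportion to
  its excursion outside the interval spanned by the two temporal
  neighbours' thickness, after the neighbours' maps are pulled into the
  current frame by a demons registration of the smoothed tissue maps.
  The interval semantics require *two* neighbours; series endpoints evolve
  without the term, because clamping an endpoint toward its single
  neighbour systematically drags baseline and final thickness toward the
  interior and flattens genuine atrophy trends.

Updates are `dt = 0.4` gradient steps through a smoothed interface delta
(width 1.5 mm); the functions are re-initialized to signed distances every
20 iterations, nesting (WM ⊆ WM∪GM ⊆ brain) is re-enforced by pointwise
max-projection after every step, and thickness/curvature fields are
refreshed every 5 and 3 iterations respectively (they vary slowly).
Initialization fits a deterministic 3-class 1-D EM (means seeded evenly
across the robust intensity range; quantile fallback on degeneracy) and
takes the max posterior of likelihood × atlas prior; the outer loop
(registration ↔ constrained evolution) stops when fewer than 0.1% of
voxels change label.

## 4D labeling

All timepoints are registered to an emergent group mean: key points
(saliency = gradient magnitude × local intensity std on a Gaussian
pyramid; greedy selection with 5-voxel minimum separation; a 5-voxel
border margin excludes filter edge artifacts), matched into each timepoint
by normalized cross-correlation of 7³ patches within an 8-voxel search
(NCC ≥ 0.6, mutual-best within 1 voxel), assembled into per-key-point
temporal trajectories, Gaussian-kernel smoothed along time (bandwidth 1
timepoint), recentred so each trajectory's temporal mean returns to its
key point (the unbiasedness of the common space), and densified into one
deformation field per timepoint by 3-D thin-plate splines (kernel
U(r) = r with exact affine part; exact interpolation at zero
regularization).  The loop repeats (default 5 rounds; studies use 3) with
the mean re-averaged from the warped images.  The atlas is registered to
the final mean symmetrically (both directions, backward field numerically
inverted and averaged), the pathways are composed per timepoint, and
labels are propagated by nearest-neighbour pullback — categorical labels,
so no new label values can appear.

## ROI analysis

ROIs are named unions of basic atlas labels, optionally intersected with a
tissue class (e.g. hippocampal GM).  Volumes are voxel counts × voxel
volume; longitudinal series are normalized by baseline and summarized by
an ordinary-least-squares slope per month.  Tables export as CSV with 8
significant digits (round-trip safe to the slope at 1e-9).

## The synthetic study generator

The phantom emulates exactly the degrees of freedom the pipeline claims to
handle: concentric, slightly ellipsoidal scalp/skull/CSF/GM/WM
compartments plus a cerebellum-like blob; linear outer-GM thinning
(default 0.025 mm/month over baseline/6/12/24 months, i.e. 3.0 → 2.4 mm);
a smooth multiplicative bias field (1 + 0.15 · sin-product, ~0.7 cycles
per field of view); additive Gaussian noise (σ = 4 against tissue means
40/80/120 for CSF/GM/WM); and small rigid jitter per follow-up (≤2 mm,
≤2°).  A fixed smooth "texture" modulation (8% RMS, 4 mm correlation
length, identical at every timepoint) is part of the anatomy: a radially
symmetric phantom has no distinctive features, which would make
feature-based registration ill-posed by construction rather than by
difficulty.  The bundled synthetic atlas is the noise-free baseline
anatomy with a smoothed brain-probability map, tissue priors, a cerebellum
mask and 10 angular-sector ROIs per hemisphere (a data-driven stand-in for
a real 45-per-hemisphere parcellation).

What the phantom does **not** model: real cortical folding (thickness here
is a spherical shell), partial-volume mixtures beyond a 0.6 mm blur,
Rician noise statistics, susceptibility or motion artifacts, and genuinely
nonrigid longitudinal anatomy outside the GM shell.  Passing studies
therefore demonstrate the correctness and the temporal-consistency
behaviour of the algorithms, not clinical-grade accuracy on real MRI.

## Evaluation studies and problem sizes

The bundled experiments run the default 96³ study for extraction accuracy
(Jaccard ≥ 0.95 per timepoint at 300 iterations) and segmentation accuracy
(per-tissue Dice ≥ 0.90; baseline shell MAE ≤ 0.3 mm; thinning slope
within 25%), 64³ repeated-seed studies for the paired consistency
comparisons (across-timepoint std of brain volume and of mean thickness,
with vs. without the temporal terms) and for ROI labeling on known smooth
warps (mean Dice ≥ 0.85), and closed-form checks (the hippocampal trend
example, TPS exactness, analytic sphere volumes, the 24 right-handed
orientations).  The consistency phantoms keep the full 3 mm shell and omit
the cerebellum blob, whose bulk geometry has no shell thickness to
stabilize.  These sizes were chosen as the smallest at which the effects
under study are comfortably above discretization noise.

## Known limitations

* The demons and affine stages assume intensity-comparable inputs; the
  atlas template drives all atlas-to-subject warps for that reason.
* Thickness is the sum of unsigned distances to the two interfaces — exact
  for slabs and concentric shells, biased in high-curvature gyral geometry
  (not modelled here).
* The temporal thickness term needs two neighbours; two-timepoint series
  get groupwise extraction/labeling consistency but no thickness clamp.
* The level-set data term sees only scalar T1-like intensity; multi-channel
  inputs are out of scope.
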