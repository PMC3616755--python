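"""Consistent 4D skull stripping of a longitudinal study.

Runs the full extraction stage (groupwise affine alignment, probability-map
warping, common-sphere initialization, joint surface evolution) and scores
each timepoint's mask against the phantom truth with the Jaccard overlap.
"""

import numpy as np

from longbrain import ForceWeights, PhantomSpec, extract_series, generate_phantom

spec = PhantomSpec()
series, truth, atlas = generate_phantom(spec)

res = extract_series(series, atlas.template, atlas.brain_probability,
                     w=ForceWeights(iters=300))

print("timepoint  Jaccard(mask, truth)   volume (mm^3)")
for t, mask in enumerate(res.brain_masks):
    est = mask.voxels > 0
    tr = truth.brain_masks[t]
    jac = (est & tr).sum() / (est | tr).sum()
    print(f"t{t:02d}        {jac:8.4f}          {est.sum():12.0f}")

print("\nJaccard above 0.95 at every timepoint means the evolved surfaces "
      "track the true brain envelope; the temporal smoothness force keeps "
      "the four volumes from jittering independently.")
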