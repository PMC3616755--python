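"""Consistent ROI labeling through the group mean.

Creates a series by warping the atlas with known smooth deformations,
recovers the deformation pathway timepoint -> group mean -> atlas with the
keypoint/trajectory/TPS machinery, propagates the parcellation, and scores
it against the identically warped truth labels.
"""

import numpy as np

from longbrain.experiments import labeling_study

res = labeling_study(seed=0)
print("per-timepoint mean ROI Dice:",
      np.round(res["per_timepoint"], 4))
print(f"overall mean ROI Dice: {res['mean_roi_dice']:.4f}")
print(f"across-timepoint std of ROI volumes: {res['roi_volume_std']:.1f} "
      "voxels")
print("\nDice above 0.85 against the known-warp truth shows the composed "
      "deformation pathway lands each parcel on the right anatomy at "
      "every timepoint.")
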