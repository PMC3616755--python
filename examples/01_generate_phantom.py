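"""Generate a synthetic longitudinal study and inspect its ground truth.

Builds the default 4-timepoint head phantom (96-cube, 1 mm voxels, GM
thinning of 0.025 mm/month, bias field, noise, rigid jitter) and prints the
true brain volume and cortical thickness per timepoint.
"""

import numpy as np

from longbrain import PhantomSpec, generate_phantom

spec = PhantomSpec()
series, truth, atlas = generate_phantom(spec)

print("timepoint  months  brain volume (mm^3)  GM thickness (mm)")
for t, month in enumerate(spec.timepoints):
    vol = truth.brain_masks[t].sum() * float(np.prod(spec.spacing))
    print(f"t{t:02d}        {month:6.1f}  {vol:18.0f}  {truth.thickness[t]:9.2f}")

print("\nThe brain volume is essentially constant (atrophy moves GM into "
      "CSF inside the same brain envelope) while the cortical shell thins "
      "from 3.0 to 2.4 mm over 24 months — the signal the 4D pipeline is "
      "built to recover smoothly.")
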