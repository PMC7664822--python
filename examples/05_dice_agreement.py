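"""Inter-observer segmentation agreement via the DICE coefficient.

Emulates a second observer by eroding or dilating each generated mask by
one voxel, then reports per-lesion DICE with the conventional > 0.7
excellent-agreement flag and the cohort mean +/- sd.
"""

import numpy as np
from scipy import ndimage

from nodtex import ROIMask, SyntheticCohortConfig, generate_cohort
from nodtex.roi_io import dice_report

cfg = SyntheticCohortConfig(n_class_nch=4, n_class_aca=4, seed=21)
lesions, _ = generate_cohort(cfg)

rng = np.random.default_rng(0)
pairs = []
for lesion in lesions:
    op = ndimage.binary_erosion if rng.random() < 0.5 else ndimage.binary_dilation
    pairs.append((lesion.mask, ROIMask(op(lesion.mask.data))))

report = dice_report(pairs)
print(report.round(3).to_string(index=False))
print("\nA coefficient above 0.7 is read as excellent agreement; one-voxel "
      "boundary differences on solid lesions stay well above it.")
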