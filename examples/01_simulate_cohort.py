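"""Generate a small synthetic two-class nodule cohort and inspect it.

Builds 5 hamartoma-like (NCH) and 5 adenocarcinoma-like (ACA) lesions,
writes them as NIfTI volume/mask pairs plus a labels.csv, and prints the
label table.  Diameters follow the class-specific distributions
(NCH smaller, ~14 mm; ACA larger, ~23 mm) and no lesion voxel reaches the
120 HU calcification bound.
"""

import tempfile
from pathlib import Path

from nodtex import SyntheticCohortConfig, generate_cohort, write_cohort

cfg = SyntheticCohortConfig(n_class_nch=5, n_class_aca=5, seed=42)
lesions, table = generate_cohort(cfg)

out = Path(tempfile.mkdtemp(prefix="nodtex_cohort_"))
write_cohort(lesions, table, out)

print(table.to_string(index=False))
print(f"\nwrote {len(lesions)} volume/mask pairs to {out}")
hu_max = max(l.volume.data[l.mask.data].max() for l in lesions)
print(f"max in-lesion attenuation: {hu_max:.1f} HU (< 120, non-calcified)")
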