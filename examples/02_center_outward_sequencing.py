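"""Split a scan into center-outward half-sequences and reassemble it.

The recurrent models read tumors from the most salient (center) slice
outward in both axial directions. This example shows the index
bookkeeping: both halves start at the center slice, and merging places
every slice back while averaging the shared center.
"""

import dataclasses

import numpy as np

from sarc_unet.phantom import PhantomConfig, generate_phantom
from sarc_unet.preprocess import merge_halves, split_at_center

scan, gtv, center_z = generate_phantom(
    PhantomConfig(grid_shape=(63, 64, 64), center_z=31, seed=7)
)  # 63 = 2*32-1 slices: two 32-step halves cover the volume exactly
inferior, superior = split_at_center(scan, center_z, pad_length=32)

print(f"center slice:        {center_z}")
print(f"inferior indices:    {inferior.source_indices[:5]} ... (valid {inferior.valid_length})")
print(f"superior indices:    {superior.source_indices[:5]} ... (valid {superior.valid_length})")
print(f"half shape:          {inferior.data.shape}  (steps, H, W, channels=CT+PET)")

# feed the CT channel through as a stand-in "prediction" and reassemble
pi = dataclasses.replace(inferior, data=inferior.data[..., :1])
ps = dataclasses.replace(superior, data=superior.data[..., :1])
merged = merge_halves(pi, ps, scan.shape[0])
err = np.abs(merged - scan.ct).max()
print(f"round-trip max error: {err:.2e}  (identity when the volume fits both halves)")
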