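"""Calibrate a noisy phantom scan, segment it and score against truth.

Mirrors the image-based workflow: two-point HU calibration from water/air
sample regions, midpoint-threshold masks with morphological cleanup, and a
Dice overlap score per part.
"""

import numpy as np

from tmjfem import PhantomConfig, build_phantom, calibrate, dice
from tmjfem.workflow import segment_phantom

raw, truth = build_phantom(PhantomConfig(shape=(60, 60, 45), spacing=0.6,
                                         noise_sd=30.0, seed=2))

centers = raw.voxel_centers()
water = raw.data[np.all((centers >= truth.water_box[0])
                        & (centers <= truth.water_box[1]), axis=-1)].mean()
air = raw.data[np.all((centers >= truth.air_box[0])
                      & (centers <= truth.air_box[1]), axis=-1)].mean()
hu = calibrate(raw, mean_water=water, mean_air=air)
print(f"calibration references: water={water:.1f}, air={air:.1f} (raw units)")

labels = segment_phantom(hu, truth, prosthesis_source="segmented")
for name in truth.labels.names.values():
    if name == "dummy_screws":
        continue
    d = dice(labels.mask(name), truth.labels.mask(name))
    print(f"  Dice({name}) = {d:.4f}")
print("\nDice = 1 means the mask matches the ground truth voxel for voxel; "
      "values near 1 under 30 HU noise show the threshold+cleanup chain is "
      "robust at clinical noise levels.")
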