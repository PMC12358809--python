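"""Crop and normalize a registered volume, as the T1 pipeline tail does.

At full scale a 182x218x182 registered image is cropped with the fixed
border window [6:173, 2:214, 0:160] to 167x212x160 and intensities are
mapped to [0, 1] by dividing by 255.
"""

import numpy as np

from braingap.preprocess import REFERENCE_CROP, CropWindow, crop_volume, normalize_intensity
from braingap.synthetic_data import Volume

full = Volume(np.random.default_rng(0).integers(0, 256, (182, 218, 182)).astype(np.uint8),
              subject_id="demo")
cropped = crop_volume(full)  # default window is the full-scale border crop
print(f"crop window {REFERENCE_CROP}: {full.shape} -> {cropped.shape}")

normalized = normalize_intensity(cropped)
print(f"intensity range after /255: [{normalized.min():.3f}, {normalized.max():.3f}]")
# 167x212x160 in [0,1] is exactly what the SFCN backbone consumes.

# desk-scale data uses an explicit window with the same half-open convention
desk = Volume(np.zeros((32, 40, 32), dtype=np.uint8), subject_id="desk")
window = CropWindow(((2, 30), (4, 36), (0, 32)))
print(f"desk-scale window {window.bounds}: {desk.shape} -> {crop_volume(desk, window).shape}")
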