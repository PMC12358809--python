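"""In-scope tail of the T1 pipeline: fixed border crop and /255 normalization.

Skull-stripping, reorientation and linear registration are external-tool
stages; volumes entering this module are assumed already registered (the
synthetic generator renders them that way).  The crop window uses the
0-based half-open Python slicing convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ShapeError, ValidationError
from .synthetic_data import Volume

# Border crop applied to 182x218x182 registered volumes -> 167x212x160
REFERENCE_CROP: tuple[tuple[int, int], ...] = ((6, 173), (2, 214), (0, 160))
REFERENCE_INPUT_SHAPE = (182, 218, 182)


@dataclass(frozen=True)
class CropWindow:
    """Half-open [start, stop) window per spatial axis."""

    bounds: tuple[tuple[int, int], ...] = REFERENCE_CROP

    def __post_init__(self) -> None:
        for lo, hi in self.bounds:
            if not (0 <= lo < hi):
                raise ValidationError(f"crop bounds must satisfy 0 <= start < stop, got {self.bounds}")

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(hi - lo for lo, hi in self.bounds)


def crop_volume(vol: Volume, window: CropWindow | None = None) -> Volume:
    """Crop a registered volume to the fixed border window."""
    window = window or CropWindow()
    shape = vol.voxels.shape
    if any(hi > s for (lo, hi), s in zip(window.bounds, shape)):
        raise ShapeError(
            f"input shape {tuple(shape)} smaller than crop window "
            f"{window.bounds} (needs at least {tuple(hi for _, hi in window.bounds)})")
    sl = tuple(slice(lo, hi) for lo, hi in window.bounds)
    return Volume(voxels=vol.voxels[sl].copy(), subject_id=vol.subject_id)


def normalize_intensity(vol: Volume | np.ndarray) -> np.ndarray:
    """Map 8-bit intensities to [0, 1] by dividing by 255."""
    vox = vol.voxels if isinstance(vol, Volume) else np.asarray(vol)
    if vox.min() < 0 or vox.max() > 255:
        raise ValidationError(
            f"intensities outside [0, 255]: range [{vox.min()}, {vox.max()}]")
    return (vox / 255.0).astype(np.float32)
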