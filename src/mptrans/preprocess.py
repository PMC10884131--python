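"""Dataset-pairing chain: slice alignment, resampling, bit-depth and scale.

The pairing convention brings both modalities onto a common grid: the
reference stack's slice count is matched to the attenuated stack's by
nearest-neighbour selection along the long axis (no intensity
interpolation), the coarser in-plane grid is magnified by the pixel-size
ratio and centre-cropped, intensities are stored as 8-bit PNG with a
per-stack linear scale, and the 8-bit values map onto a 0-100 uptake scale
(255 -> 100).  Network-facing images are bilinearly resized up to the
model's matrix size and back down afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .stacks import UPTAKE_MAX, ImageStack


@dataclass
class ScaleRecord:
    """Bookkeeping for an exact 8-bit round trip."""

    max_value: float           # stack maximum mapped to 255 (0 for all-zero stacks)
    interpolation: str = "bilinear"

    @property
    def per_level(self) -> float:
        return self.max_value / 255.0 if self.max_value > 0 else 0.0


def align_slice_counts(pet: ImageStack, n_target: int) -> ImageStack:
    """Select ``n_target`` slices by nearest physical long-axis position.

    Target slab centres are laid out uniformly over the input stack's
    physical extent; each output slice is a copy of the input slice whose
    centre is nearest (ties broken toward the base).  Intensities are never
    interpolated.
    """
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    if pet.n_slices < 1:
        raise ValueError("empty stack")
    if n_target == pet.n_slices:
        return pet.copy_with()
    extent = pet.n_slices * pet.slice_mm
    out_thickness = extent / n_target
    in_pos = pet.slice_positions_mm()
    out_pos = (np.arange(n_target) + 0.5) * out_thickness
    picks = np.abs(out_pos[:, None] - in_pos[None, :]).argmin(axis=1)
    return pet.copy_with(voxels=pet.voxels[picks].copy(), slice_mm=out_thickness)


def resample_and_crop(
    spect: ImageStack, target_pixel_mm: float, out_size: int
) -> ImageStack:
    """Magnify in-plane by pixel_mm / target_pixel_mm, then centre-crop.

    The retained window covers ``out_size * target_pixel_mm`` millimetres
    centred on the magnified image.
    """
    if target_pixel_mm <= 0:
        raise ValueError("target_pixel_mm must be positive")
    if spect.pixel_mm < target_pixel_mm:
        raise ValueError("target pixel must not be finer-to-coarser inverted")
    factor = spect.pixel_mm / target_pixel_mm
    size = spect.size
    new_size = int(round(size * factor))
    if new_size < out_size:
        raise ValueError(
            f"magnified image ({new_size}px) smaller than requested crop ({out_size}px)"
        )
    if new_size == size:
        magnified = spect.voxels.astype(float)
    else:
        magnified = np.stack(
            [
                resize(
                    s, (new_size, new_size), order=1,
                    mode="edge", anti_aliasing=False, preserve_range=True,
                )
                for s in spect.voxels
            ]
        )
    lo = (new_size - out_size) // 2
    cropped = magnified[:, lo : lo + out_size, lo : lo + out_size]
    if spect.is_uptake:
        cropped = np.clip(cropped, 0.0, UPTAKE_MAX)
    return spect.copy_with(voxels=cropped.copy(), pixel_mm=target_pixel_mm)


def to_uint8(stack: ImageStack) -> tuple[ImageStack, ScaleRecord]:
    """Linear per-stack map of the maximum to 255, rounded to 8 bits."""
    v = stack.voxels
    if v.min() < 0:
        raise ValueError("negative intensities cannot be 8-bit encoded")
    m = float(v.max())
    if m == 0.0:
        data8 = np.zeros_like(v, dtype=np.uint8)
        record = ScaleRecord(max_value=0.0)
    else:
        data8 = np.round(v * (255.0 / m)).astype(np.uint8)
        record = ScaleRecord(max_value=m)
    return stack.copy_with(voxels=data8, is_uptake=False), record


def from_uint8(stack: ImageStack, record: ScaleRecord) -> ImageStack:
    """Invert :func:`to_uint8` (exact on the 256 quantized levels)."""
    if stack.is_uptake:
        raise ValueError("stack is already on the uptake scale")
    v = stack.voxels.astype(float) * record.per_level
    return stack.copy_with(voxels=v, is_uptake=False)


def to_uptake(stack: ImageStack) -> ImageStack:
    """8-bit value v -> 100 * v / 255 on the uptake scale."""
    if stack.is_uptake:
        raise ValueError("stack is already on the uptake scale")
    v = stack.voxels.astype(float)
    if v.min() < 0 or v.max() > 255:
        raise ValueError("8-bit input required")
    return stack.copy_with(voxels=v * (UPTAKE_MAX / 255.0), is_uptake=True)


def _resize_square(img: np.ndarray, size: int) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError("square image required")
    if img.shape[0] == size:
        return img.copy()
    return resize(
        img, (size, size), order=1, mode="edge", anti_aliasing=False, preserve_range=True
    )


def resize_for_network(img: np.ndarray, size: int) -> np.ndarray:
    """Bilinear upsizing to the model's matrix size."""
    return _resize_square(img, size)


def downsize_after_network(img: np.ndarray, size: int) -> np.ndarray:
    """Bilinear downsizing back to the acquisition matrix size."""
    return _resize_square(img, size)


def preprocess_pair(
    spect: ImageStack, pet: ImageStack, *, target_pixel_mm: float | None = None,
    out_size: int | None = None,
) -> tuple[ImageStack, ImageStack]:
    """Full pairing chain for one patient: align the reference stack's
    slice count to the attenuated stack's, then bring the attenuated stack
    onto the reference in-plane grid."""
    target_pixel_mm = pet.pixel_mm if target_pixel_mm is None else target_pixel_mm
    out_size = pet.size if out_size is None else out_size
    pet_aligned = align_slice_counts(pet, spect.n_slices)
    spect_matched = resample_and_crop(spect, target_pixel_mm, out_size)
    return spect_matched, pet_aligned
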