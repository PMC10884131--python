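"""Short-axis image stacks and their on-disk representation.

An :class:`ImageStack` is the common currency of the pipeline: an ordered
base-to-apex array of square short-axis slices together with the physical
geometry (in-plane pixel size, slice thickness) and acquisition metadata
(stress/rest state, modality).  Stacks are written to disk as one 8-bit
grayscale PNG per slice plus a plain-text sidecar holding the metadata, so
every intermediate product of the pipeline is inspectable with standard
image tools.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

VALID_STATES = ("stress", "rest")
VALID_MODALITIES = ("spect", "pet", "spect_spt")

UPTAKE_MAX = 100.0


@dataclass
class ImageStack:
    """Ordered base-to-apex stack of square short-axis slices.

    Parameters
    ----------
    voxels
        Array of shape ``(slices, rows, cols)``.  Interpreted on the
        0-100 uptake scale when ``is_uptake`` is True, otherwise as raw
        (e.g. 8-bit) intensities.
    pixel_mm
        In-plane pixel size in millimetres (square pixels).
    slice_mm
        Slice thickness in millimetres.
    state
        ``"stress"`` or ``"rest"``.
    modality
        ``"spect"``, ``"pet"`` or ``"spect_spt"``.
    is_uptake
        Whether ``voxels`` is on the 0-100 uptake scale.
    """

    voxels: np.ndarray
    pixel_mm: float
    slice_mm: float
    state: str = "stress"
    modality: str = "spect"
    is_uptake: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be (slices, rows, cols)")
        n, r, c = self.voxels.shape
        if n < 1:
            raise ValueError("stack must contain at least one slice")
        if r != c:
            raise ValueError(f"slices must be square, got {r}x{c}")
        if self.pixel_mm <= 0 or self.slice_mm <= 0:
            raise ValueError("pixel_mm and slice_mm must be positive")
        if self.state not in VALID_STATES:
            raise ValueError(f"state must be one of {VALID_STATES}")
        if self.modality not in VALID_MODALITIES:
            raise ValueError(f"modality must be one of {VALID_MODALITIES}")
        if self.is_uptake:
            v = self.voxels
            if v.size and (np.nanmin(v) < -1e-9 or np.nanmax(v) > UPTAKE_MAX + 1e-9):
                raise ValueError("uptake-flagged voxels must lie in [0, 100]")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def size(self) -> int:
        return self.voxels.shape[1]

    def slice_positions_mm(self) -> np.ndarray:
        """Physical long-axis position of each slab centre, measured from
        the basal edge of the basal-most slice."""
        return (np.arange(self.n_slices) + 0.5) * self.slice_mm

    def copy_with(self, **kwargs) -> "ImageStack":
        if "voxels" not in kwargs:
            kwargs["voxels"] = self.voxels.copy()
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Disk I/O: per-slice 8-bit PNG + plain-text sidecar
# ---------------------------------------------------------------------------

_SIDECAR_KEYS = ("pixel_mm", "slice_mm", "state", "modality", "n_slices", "uptake_scale")


def _slice_name(case: str, state: str, modality: str, index: int) -> str:
    return f"{case}_{state}_{modality}_{index:03d}.png"


def write_stack(stack: ImageStack, out_dir: str | Path, case: str) -> Path:
    """Write a stack as per-slice 8-bit grayscale PNGs plus a sidecar.

    Uptake-scale stacks are stored with the exact 0-100 -> 0-255 linear map
    (uptake u -> round(u * 255 / 100)) so that reading back through
    :func:`read_stack` is the standard uptake conversion.  Returns the
    sidecar path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if stack.is_uptake:
        data8 = np.round(stack.voxels * 255.0 / UPTAKE_MAX).astype(np.uint8)
    else:
        v = stack.voxels
        if v.min() < 0 or v.max() > 255:
            raise ValueError("raw stack values outside [0, 255]")
        data8 = np.round(v).astype(np.uint8)
    for i in range(stack.n_slices):
        Image.fromarray(data8[i], mode="L").save(
            out_dir / _slice_name(case, stack.state, stack.modality, i)
        )
    sidecar = out_dir / f"{case}_{stack.state}_{stack.modality}.meta.txt"
    lines = [
        f"pixel_mm: {stack.pixel_mm!r}",
        f"slice_mm: {stack.slice_mm!r}",
        f"state: {stack.state}",
        f"modality: {stack.modality}",
        f"n_slices: {stack.n_slices}",
        f"uptake_scale: {int(stack.is_uptake)}",
    ]
    sidecar.write_text("\n".join(lines) + "\n")
    return sidecar


def read_stack(sidecar: str | Path) -> ImageStack:
    """Read a stack written by :func:`write_stack` from its sidecar path."""
    sidecar = Path(sidecar)
    meta: dict[str, str] = {}
    for line in sidecar.read_text().splitlines():
        if ":" in line:
            k, v = line.split(":", 1)
            meta[k.strip()] = v.strip()
    missing = [k for k in _SIDECAR_KEYS if k not in meta]
    if missing:
        raise ValueError(f"sidecar {sidecar} missing keys: {missing}")
    m = re.match(r"(.+)_(stress|rest)_(spect|pet|spect_spt)\.meta\.txt$", sidecar.name)
    if not m:
        raise ValueError(f"unrecognized sidecar name: {sidecar.name}")
    case, state, modality = m.groups()
    n = int(meta["n_slices"])
    slices = []
    for i in range(n):
        p = sidecar.parent / _slice_name(case, state, modality, i)
        slices.append(np.asarray(Image.open(p).convert("L"), dtype=np.float64))
    voxels = np.stack(slices)
    is_uptake = bool(int(meta["uptake_scale"]))
    if is_uptake:
        voxels = voxels * UPTAKE_MAX / 255.0
    return ImageStack(
        voxels=voxels,
        pixel_mm=float(meta["pixel_mm"]),
        slice_mm=float(meta["slice_mm"]),
        state=state,
        modality=modality,
        is_uptake=is_uptake,
        meta={"case": case},
    )
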