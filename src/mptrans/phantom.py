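"""Synthetic paired myocardial perfusion stacks with known ground truth.

Generates left-ventricular short-axis phantoms as annular "myocardium"
rings tapering toward a filled-disc apex, evaluated analytically at either
modality's voxel grid: the reference ("PET-like") geometry uses 1.6 mm
pixels / 1.6 mm slices and the attenuated ("SPECT-like") geometry 2.4 mm /
2.4 mm, both square matrices.  True perfusion defects are applied per AHA
segment, and a spatially smooth attenuation field -- an angular
raised-cosine bump aimed at the inferior wall times a per-ring multiplier
-- depresses SPECT counts the way photon absorption does in practice.

Noise is a signed Gaussian perturbation scaled by sqrt(intensity)
(Poisson-like), clipped to [0, 100].  Everything is deterministic for a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .segment17 import (
    N_SEGMENTS,
    RING_NAMES,
    SlabPartition,
    partition_slabs,
    sector_of_angle,
)
from .stacks import ImageStack, write_stack

INFERIOR_DEG = 180.0  # inferior wall under the fixed angular convention


@dataclass
class PhantomConfig:
    """Geometry and intensity parameters of one synthetic patient."""

    matrix_size: int = 128
    pet_pixel_mm: float = 1.6
    spect_pixel_mm: float = 2.4
    pet_slice_mm: float = 1.6
    spect_slice_mm: float = 2.4
    lv_length_mm: float = 76.8
    ring_center: tuple[float, float] | None = None  # (row, col) px; None = image centre
    endo_radius_mm: float = 18.0
    epi_radius_mm: float = 28.0
    apex_taper: float = 0.35  # fractional radius shrink at the apex end
    baseline_uptake: float = 80.0
    noise_scale: float = 0.0
    noise_corr_mm: float = 4.8  # spatial correlation length of the noise field
    blur_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.matrix_size % 2 != 0:
            raise ValueError("matrix_size must be even")
        if not 0 < self.baseline_uptake <= 100:
            raise ValueError("baseline_uptake must lie in (0, 100]")
        if self.endo_radius_mm >= self.epi_radius_mm:
            raise ValueError("endo radius must be smaller than epi radius")
        if not 0 <= self.apex_taper < 1:
            raise ValueError("apex_taper must lie in [0, 1)")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be nonnegative")

    def n_slices(self, modality: str) -> int:
        mm = self.spect_slice_mm if modality == "spect" else self.pet_slice_mm
        return max(1, int(round(self.lv_length_mm / mm)))

    def pixel_mm(self, modality: str) -> float:
        return self.spect_pixel_mm if modality == "spect" else self.pet_pixel_mm

    def center_px(self, modality: str) -> tuple[float, float]:
        if self.ring_center is not None:
            return self.ring_center
        c = (self.matrix_size - 1) / 2.0
        return (c, c)

    def taper(self, slice_index: int, n_slices: int) -> float:
        """Radius multiplier for a slice, shrinking linearly base -> apex."""
        if n_slices == 1:
            return 1.0
        return 1.0 - self.apex_taper * slice_index / (n_slices - 1)


@dataclass
class DefectSpec:
    """A true perfusion defect over a set of AHA segments."""

    segments: tuple[int, ...]
    severity: float
    state: str = "both"  # stress | rest | both

    def __post_init__(self) -> None:
        self.segments = tuple(self.segments)
        if not self.segments:
            raise ValueError("defect needs at least one segment")
        if any(not 1 <= s <= N_SEGMENTS for s in self.segments):
            raise ValueError("segments must lie in 1..17")
        if not 0 <= self.severity <= 1:
            raise ValueError("severity must lie in [0, 1]")
        if self.state not in ("stress", "rest", "both"):
            raise ValueError("state must be stress, rest or both")

    def applies_to(self, state: str) -> bool:
        return self.state == "both" or self.state == state


@dataclass
class AttenuationSpec:
    """Smooth multiplicative attenuation aimed at the inferior wall."""

    min_factor: float = 0.8
    peak_direction_deg: float = INFERIOR_DEG
    angular_width_deg: float = 150.0
    longitudinal_profile: tuple[float, float, float, float] = (1.0, 1.0, 0.7, 0.4)

    def __post_init__(self) -> None:
        if not 0 < self.min_factor <= 1:
            raise ValueError("min_factor must lie in (0, 1]")
        if self.angular_width_deg <= 0:
            raise ValueError("angular_width_deg must be positive")
        if len(self.longitudinal_profile) != len(RING_NAMES):
            raise ValueError("longitudinal_profile needs one entry per ring")
        if any(not 0 <= p <= 1 for p in self.longitudinal_profile):
            raise ValueError("longitudinal multipliers must lie in [0, 1]")

    def angular_bump(self, angle_deg: np.ndarray) -> np.ndarray:
        """Raised cosine in angle: 1 at the peak direction, 0 outside the lobe."""
        delta = (np.asarray(angle_deg, dtype=float) - self.peak_direction_deg + 180.0) % 360.0 - 180.0
        half = self.angular_width_deg / 2.0
        bump = 0.5 * (1.0 + np.cos(np.pi * delta / half))
        return np.where(np.abs(delta) <= half, bump, 0.0)


@dataclass
class PhantomTruth:
    """Ground truth carried alongside a simulated patient pair."""

    true_segment_values: np.ndarray      # (17,) uptake scale
    defect_map: np.ndarray               # bool, SPECT geometry
    attenuation_field: np.ndarray        # (0,1] factors, SPECT geometry

    def __post_init__(self) -> None:
        self.true_segment_values = np.asarray(self.true_segment_values, dtype=float)
        if self.true_segment_values.shape != (N_SEGMENTS,):
            raise ValueError("expected 17 true segment values")
        if np.any(self.true_segment_values < 0) or np.any(self.true_segment_values > 100):
            raise ValueError("true segment values must lie in [0, 100]")
        if self.defect_map.shape != self.attenuation_field.shape:
            raise ValueError("defect map and attenuation field shapes must match")


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def voxel_angles_deg(size: int, center: tuple[float, float]) -> np.ndarray:
    """Angle of every pixel relative to ``center`` under the package's
    angular convention (0 = anterior/up, 90 = septum/left, 180 = inferior)."""
    rows, cols = np.mgrid[0:size, 0:size].astype(float)
    dr = rows - center[0]
    dc = cols - center[1]
    return np.degrees(np.arctan2(-dc, -dr)) % 360.0


def segment_label_map(
    size: int, center: tuple[float, float], partition: SlabPartition
) -> np.ndarray:
    """Per-voxel AHA segment number (1..17) for a stack of ``len(partition)``
    slices, from each voxel's (ring, angle) location."""
    angles = voxel_angles_deg(size, center)
    n = len(partition.slab_of_slice)
    out = np.zeros((n, size, size), dtype=np.int8)
    ring_sector_lut = {}
    for ring in RING_NAMES:
        lut = np.array([sector_of_angle(a + 0.5, ring) for a in range(360)], dtype=np.int8)
        ring_sector_lut[ring] = lut
    idx = np.minimum(angles.astype(int), 359)
    for i, ring in enumerate(partition.slab_of_slice):
        out[i] = ring_sector_lut[ring][idx]
    return out


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def make_ring_slice(
    config: PhantomConfig, slice_index: int, modality: str = "spect"
) -> np.ndarray:
    """One noise-free short-axis slice: an annulus of ``baseline_uptake``
    on background 0, radii tapered toward the apex; apex-slab slices are
    filled discs."""
    n = config.n_slices(modality)
    if not 0 <= slice_index < n:
        raise ValueError(f"slice_index {slice_index} outside stack of {n}")
    t = config.taper(slice_index, n)
    endo = config.endo_radius_mm * t
    epi = config.epi_radius_mm * t
    if endo >= epi:
        raise ValueError("degenerate radii: endo >= epi after taper")
    partition = partition_slabs(n)
    if partition.slab_of_slice[slice_index] == "apex":
        endo = 0.0
    size = config.matrix_size
    center = config.center_px(modality)
    px = config.pixel_mm(modality)
    rows, cols = np.mgrid[0:size, 0:size].astype(float)
    r_mm = np.hypot(rows - center[0], cols - center[1]) * px
    img = np.where((r_mm >= endo) & (r_mm <= epi), config.baseline_uptake, 0.0)
    if config.blur_mm > 0:
        img = gaussian_filter(img, sigma=config.blur_mm / px)
    return img


def make_ring_stack(config: PhantomConfig, modality: str, state: str = "stress") -> ImageStack:
    """Noise-free, defect-free, attenuation-free phantom stack."""
    n = config.n_slices(modality)
    voxels = np.stack([make_ring_slice(config, i, modality) for i in range(n)])
    return ImageStack(
        voxels=voxels,
        pixel_mm=config.pixel_mm(modality),
        slice_mm=config.spect_slice_mm if modality == "spect" else config.pet_slice_mm,
        state=state,
        modality=modality,
    )


def apply_defect(
    stack: ImageStack,
    truth_geometry: tuple[tuple[float, float], SlabPartition],
    defect: DefectSpec,
) -> ImageStack:
    """Multiply voxels mapping to the defect's segments by (1 - severity).

    ``truth_geometry`` is the (centre, slab partition) pair that defines
    the voxel -> segment mapping.  Defects restricted to the other
    physiological state leave the stack unchanged.
    """
    if not defect.applies_to(stack.state):
        return stack.copy_with()
    center, partition = truth_geometry
    labels = segment_label_map(stack.size, center, partition)
    mask = np.isin(labels, defect.segments)
    voxels = stack.voxels.copy()
    voxels[mask] *= 1.0 - defect.severity
    return stack.copy_with(voxels=voxels)


def attenuation_field_for(
    spec: AttenuationSpec, size: int, center: tuple[float, float], partition: SlabPartition
) -> np.ndarray:
    """Per-voxel multiplicative factor in (0, 1] for a stack's geometry."""
    angles = voxel_angles_deg(size, center)
    bump = spec.angular_bump(angles)
    depth = 1.0 - spec.min_factor
    ring_index = {name: i for i, name in enumerate(RING_NAMES)}
    field_ = np.empty((len(partition.slab_of_slice), size, size))
    for i, ring in enumerate(partition.slab_of_slice):
        mult = spec.longitudinal_profile[ring_index[ring]]
        field_[i] = 1.0 - depth * bump * mult
    return field_


def apply_attenuation(
    stack: ImageStack, spec: AttenuationSpec, center: tuple[float, float] | None = None
) -> tuple[ImageStack, np.ndarray]:
    """Depress counts by the smooth attenuation field; returns the field
    too so it can be recorded as ground truth."""
    if center is None:
        c = (stack.size - 1) / 2.0
        center = (c, c)
    partition = partition_slabs(stack.n_slices)
    field_ = attenuation_field_for(spec, stack.size, center, partition)
    return stack.copy_with(voxels=stack.voxels * field_), field_


def _add_noise(
    voxels: np.ndarray,
    noise_scale: float,
    rng: np.random.Generator,
    corr_mm: float = 0.0,
    pixel_mm: float = 1.0,
) -> np.ndarray:
    """Signed Gaussian perturbation scaled by sqrt(intensity), clipped.

    The noise field is spatially correlated at ``corr_mm`` (unit-variance
    after smoothing) so that its statistics are comparable between voxel
    grids of different pitch, as in reconstructed emission images.
    """
    if noise_scale == 0:
        return voxels.copy()
    field_ = rng.standard_normal(voxels.shape)
    if corr_mm > 0:
        sigma_px = corr_mm / pixel_mm
        field_ = gaussian_filter(field_, sigma=(0, sigma_px, sigma_px))
        field_ /= field_.std()
    noisy = voxels + noise_scale * np.sqrt(np.maximum(voxels, 0.0)) * field_
    return np.clip(noisy, 0.0, 100.0)


def generate_patient_pair(
    config: PhantomConfig,
    defects: list[DefectSpec] | None = None,
    attenuation: AttenuationSpec | None = None,
    seed: int | None = None,
    state: str = "stress",
) -> tuple[ImageStack, ImageStack, PhantomTruth]:
    """Simulate one patient: attenuated SPECT stack, reference PET stack,
    and the ground truth (true segment values, defect map, attenuation
    field).  Identical anatomy underlies both stacks; they differ only by
    sampling geometry, attenuation and noise.
    """
    defects = [d for d in (defects or []) if d.applies_to(state)]
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    stacks: dict[str, ImageStack] = {}
    spect_field = None
    defect_map = None
    for modality in ("pet", "spect"):
        stack = make_ring_stack(config, modality, state)
        partition = partition_slabs(stack.n_slices)
        geometry = (config.center_px(modality), partition)
        for d in defects:
            stack = apply_defect(stack, geometry, d)
        if modality == "spect":
            labels = segment_label_map(stack.size, geometry[0], partition)
            defected = sorted({s for d in defects for s in d.segments})
            defect_map = np.isin(labels, defected) if defected else np.zeros_like(labels, dtype=bool)
            if attenuation is not None:
                field_ = attenuation_field_for(attenuation, stack.size, geometry[0], partition)
                stack = stack.copy_with(voxels=stack.voxels * field_)
                spect_field = field_
            else:
                spect_field = np.ones_like(stack.voxels)
        stack = stack.copy_with(
            voxels=_add_noise(
                stack.voxels, config.noise_scale, rng,
                corr_mm=config.noise_corr_mm, pixel_mm=config.pixel_mm(modality),
            )
        )
        stacks[modality] = stack

    true_values = np.full(N_SEGMENTS, config.baseline_uptake)
    for d in defects:
        for s in d.segments:
            true_values[s - 1] *= 1.0 - d.severity
    truth = PhantomTruth(
        true_segment_values=true_values,
        defect_map=defect_map,
        attenuation_field=spect_field,
    )
    return stacks["spect"], stacks["pet"], truth


def write_truth_csv(truth: PhantomTruth, path: str | Path) -> None:
    lines = ["segment,true_value"]
    lines += [f"{i + 1},{v:.6f}" for i, v in enumerate(truth.true_segment_values)]
    Path(path).write_text("\n".join(lines) + "\n")


def write_patient_pair(
    out_dir: str | Path,
    case: str,
    spect: ImageStack,
    pet: ImageStack,
    truth: PhantomTruth,
) -> None:
    """Persist a simulated pair as PNG stacks + sidecars + truth CSV."""
    out_dir = Path(out_dir)
    write_stack(spect, out_dir, case)
    write_stack(pet, out_dir, case)
    write_truth_csv(truth, out_dir / f"{case}_{spect.state}_truth.csv")
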