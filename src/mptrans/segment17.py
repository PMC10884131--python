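"""AHA 17-segment quantification of short-axis stacks.

The representative voxel value of each segment is computed by a polar
profile procedure: every short-axis slice is sampled along 360 radial rays
(one per integer degree) from the left-ventricular centre, the maximum
intensity along each ray is recorded, and each segment's value is the mean
of the per-angle maxima over all (angle x slice) profiles belonging to it.

Longitudinally the stack is divided into seven near-equal divisions; the
first two form the basal ring, the next two the mid ring, the following two
the apical ring, and the last one the apex.  Basal and mid rings are split
into six 60-degree sectors (segments 1-6 and 7-12), the apical ring into
four 90-degree sectors (13-16), and the apex slab contributes segment 17
only (all 360 profiles of its slices).

Angular convention (fixed globally, see also :mod:`mptrans.phantom`):
0 degrees points at the anterior wall (up in a standard short-axis
display), angles increase toward the septum (counter-clockwise on screen),
so the inferior wall sits at 180 degrees.  Segment 1 (basal anterior) is
centred on 0 degrees and spans [-30, 30).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .stacks import ImageStack

N_SEGMENTS = 17
RING_NAMES = ("basal", "mid", "apical", "apex")

#: degrees of arc per sector in each ring
BASAL_MID_SECTOR_DEG = 60
APICAL_SECTOR_DEG = 90


@dataclass
class SlabPartition:
    """Assignment of slices to the four longitudinal rings."""

    slab_of_slice: list[str]        # per-slice ring label, base -> apex
    division_sizes: tuple[int, ...]  # the 7 longitudinal divisions (2/2/2/1)

    def __post_init__(self) -> None:
        if any(lbl not in RING_NAMES for lbl in self.slab_of_slice):
            raise ValueError("invalid ring label")
        order = [RING_NAMES.index(lbl) for lbl in self.slab_of_slice]
        if any(b < a for a, b in zip(order, order[1:])):
            raise ValueError("ring labels must be ordered base -> apex")
        if "apex" not in self.slab_of_slice:
            raise ValueError("apex slab must be nonempty")

    def slices_in(self, ring: str) -> list[int]:
        return [i for i, lbl in enumerate(self.slab_of_slice) if lbl == ring]


@dataclass
class SegmentTable:
    """Representative voxel values for the 17 AHA segments (0-100 scale)."""

    values: np.ndarray      # shape (17,), indexed by segment number - 1
    n_profiles: np.ndarray  # shape (17,), profiles averaged per segment

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.n_profiles = np.asarray(self.n_profiles, dtype=int)
        if self.values.shape != (N_SEGMENTS,) or self.n_profiles.shape != (N_SEGMENTS,):
            raise ValueError("segment tables have exactly 17 entries")
        if np.any(self.values < -1e-9) or np.any(self.values > 100 + 1e-9):
            raise ValueError("segment values must lie in [0, 100]")
        if np.any(self.n_profiles < 1):
            raise ValueError("every segment needs at least one profile")

    def value(self, segment: int) -> float:
        """Value of AHA segment ``segment`` (1-based)."""
        return float(self.values[segment - 1])


def partition_slabs(n_slices: int) -> SlabPartition:
    """Divide ``n_slices`` base-to-apex slices into the four rings.

    With at least 7 slices the stack is split into 7 near-equal longitudinal
    divisions (size difference at most one, larger divisions toward the
    base) grouped 2/2/2/1 into basal/mid/apical/apex.  Between 4 and 6
    slices the rings are populated directly (with a warning); fewer than 4
    slices cannot populate all four rings and is rejected.
    """
    if n_slices < 4:
        raise ValueError("need at least 4 slices to populate all four rings")
    if n_slices >= 7:
        q, r = divmod(n_slices, 7)
        sizes = tuple(q + (1 if i < r else 0) for i in range(7))
        ring_sizes = (sizes[0] + sizes[1], sizes[2] + sizes[3], sizes[4] + sizes[5], sizes[6])
    else:
        warnings.warn(
            f"only {n_slices} slices: rings populated directly instead of "
            "via 7 longitudinal divisions",
            stacklevel=2,
        )
        counts = [1, 1, 1, 1]
        order = [0, 1, 2]  # extras go basal, then mid, then apical
        for k in range(n_slices - 4):
            counts[order[k % 3]] += 1
        ring_sizes = tuple(counts)
        b, m, a, x = ring_sizes
        sizes = (b, 0, m, 0, a, 0, x)
    labels: list[str] = []
    for ring, cnt in zip(RING_NAMES, ring_sizes):
        labels.extend([ring] * cnt)
    return SlabPartition(slab_of_slice=labels, division_sizes=sizes)


def sector_of_angle(angle_deg: float, ring: str) -> int:
    """AHA segment number for a profile at ``angle_deg`` in ``ring``."""
    a = float(angle_deg) % 360.0
    if ring == "basal":
        return 1 + int(((a + 30.0) % 360.0) // BASAL_MID_SECTOR_DEG)
    if ring == "mid":
        return 7 + int(((a + 30.0) % 360.0) // BASAL_MID_SECTOR_DEG)
    if ring == "apical":
        return 13 + int(((a + 45.0) % 360.0) // APICAL_SECTOR_DEG)
    if ring == "apex":
        return 17
    raise ValueError(f"unknown ring {ring!r}")


def ray_direction(angle_deg: np.ndarray | float) -> tuple[np.ndarray, np.ndarray]:
    """(drow, dcol) unit vector for the fixed angular convention.

    0 deg -> anterior (up, -row); 90 deg -> septum (left, -col);
    180 deg -> inferior (down, +row); 270 deg -> lateral (right, +col).
    """
    t = np.deg2rad(angle_deg)
    return -np.cos(t), -np.sin(t)


def default_center(stack: ImageStack) -> tuple[float, float]:
    """LV centre estimate: intensity centroid of the middle slice."""
    img = stack.voxels[stack.n_slices // 2]
    total = img.sum()
    if total <= 0:
        return ((img.shape[0] - 1) / 2.0, (img.shape[1] - 1) / 2.0)
    rows, cols = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    return (float((rows * img).sum() / total), float((cols * img).sum() / total))


def radial_max_profiles(
    slice_img: np.ndarray,
    center: tuple[float, float],
    *,
    step_px: float = 0.5,
    r_min_px: float = 0.0,
    r_max_px: float | None = None,
) -> np.ndarray:
    """Per-angle radial maxima of one short-axis slice.

    For each integer angle 0..359 the intensity is sampled by bilinear
    interpolation at ``step_px`` increments along the ray from ``center``
    out to the image-inscribed radius (or ``r_max_px``), and the maximum is
    returned.  ``r_min_px``/``r_max_px`` allow restriction to a myocardial
    band; the default scans the full ray.
    """
    img = np.asarray(slice_img, dtype=float)
    if img.ndim != 2:
        raise ValueError("slice must be 2-D")
    h, w = img.shape
    cr, cc = center
    if not (0 <= cr <= h - 1 and 0 <= cc <= w - 1):
        raise ValueError("center must lie inside the image")
    inscribed = min(cr, h - 1 - cr, cc, w - 1 - cc)
    r_hi = inscribed if r_max_px is None else min(r_max_px, inscribed)
    r_hi = max(r_hi, r_min_px)
    radii = np.arange(r_min_px, r_hi + step_px / 2, step_px)
    angles = np.arange(360.0)
    drow, dcol = ray_direction(angles)
    rows = cr + np.outer(drow, radii)   # (360, n_steps)
    cols = cc + np.outer(dcol, radii)
    samples = map_coordinates(
        img, np.stack([rows.ravel(), cols.ravel()]), order=1, mode="nearest"
    ).reshape(360, radii.size)
    return samples.max(axis=1)


def segment_representative_values(
    stack: ImageStack,
    center: tuple[float, float] | None = None,
    *,
    step_px: float = 0.5,
    r_min_px: float = 0.0,
    r_max_px: float | None = None,
) -> SegmentTable:
    """Representative voxel value of each AHA segment for one stack.

    Each segment value is the mean of all per-angle radial maxima over the
    segment's (angle x slice) profile set; basal/mid sectors receive 60
    profiles per slice, apical sectors 90, and the apex slab contributes
    all 360 profiles of each of its slices to segment 17.
    """
    if not stack.is_uptake:
        raise ValueError("stack must be on the uptake scale")
    if center is None:
        center = default_center(stack)
    partition = partition_slabs(stack.n_slices)
    angles = np.arange(360)
    sums = np.zeros(N_SEGMENTS)
    counts = np.zeros(N_SEGMENTS, dtype=int)
    seg_by_ring = {
        ring: np.array([sector_of_angle(a, ring) - 1 for a in angles])
        for ring in RING_NAMES
    }
    for i in range(stack.n_slices):
        ring = partition.slab_of_slice[i]
        prof = radial_max_profiles(
            stack.voxels[i], center,
            step_px=step_px, r_min_px=r_min_px, r_max_px=r_max_px,
        )
        segs = seg_by_ring[ring]
        np.add.at(sums, segs, prof)
        np.add.at(counts, segs, 1)
    if np.any(counts == 0):
        raise ValueError("some segments received no profiles")
    return SegmentTable(values=sums / counts, n_profiles=counts)
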