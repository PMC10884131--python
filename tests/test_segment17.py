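import numpy as np
import pytest
from scipy.ndimage import gaussian_filter, rotate

from mptrans.phantom import PhantomConfig, make_ring_stack
from mptrans.segment17 import (
    SegmentTable,
    default_center,
    partition_slabs,
    radial_max_profiles,
    ray_direction,
    sector_of_angle,
    segment_representative_values,
)
from mptrans.stacks import ImageStack


# ---------------------------------------------------------------------------
# brute-force oracle: explicit loops over angle, radius, slice with manual
# bilinear lookup, independent of the vectorized implementation
# ---------------------------------------------------------------------------

def bilinear(img, r, c):
    h, w = img.shape
    r = min(max(r, 0.0), h - 1.0)
    c = min(max(c, 0.0), w - 1.0)
    r0, c0 = int(np.floor(r)), int(np.floor(c))
    r1, c1 = min(r0 + 1, h - 1), min(c0 + 1, w - 1)
    fr, fc = r - r0, c - c0
    return (
        img[r0, c0] * (1 - fr) * (1 - fc)
        + img[r0, c1] * (1 - fr) * fc
        + img[r1, c0] * fr * (1 - fc)
        + img[r1, c1] * fr * fc
    )


def brute_profiles(img, center, step=0.5):
    h, w = img.shape
    cr, cc = center
    r_hi = min(cr, h - 1 - cr, cc, w - 1 - cc)
    out = np.empty(360)
    for a in range(360):
        t = np.deg2rad(a)
        dr, dc = -np.cos(t), -np.sin(t)
        best = -np.inf
        radius = 0.0
        while radius <= r_hi + step / 2:
            best = max(best, bilinear(img, cr + dr * radius, cc + dc * radius))
            radius += step
        out[a] = best
    return out


def brute_segment_values(stack, center):
    part = partition_slabs(stack.n_slices)
    sums = np.zeros(17)
    counts = np.zeros(17)
    for i in range(stack.n_slices):
        ring = part.slab_of_slice[i]
        prof = brute_profiles(stack.voxels[i], center)
        for a in range(360):
            seg = sector_of_angle(a, ring)
            sums[seg - 1] += prof[a]
            counts[seg - 1] += 1
    return sums / counts


class TestPartitionSlabs:
    def test_14_slices_exact_divisibility(self):
        p = partition_slabs(14)
        assert p.division_sizes == (2, 2, 2, 2, 2, 2, 2)
        assert p.slices_in("basal") == [0, 1, 2, 3]

    def test_7_slices_one_per_division(self):
        p = partition_slabs(7)
        assert p.division_sizes == (1, 1, 1, 1, 1, 1, 1)
        assert p.slab_of_slice == [
            "basal", "basal", "mid", "mid", "apical", "apical", "apex",
        ]

    def test_16_slices_rounding_rule(self):
        p = partition_slabs(16)
        assert p.division_sizes == (3, 3, 2, 2, 2, 2, 2)
        assert sum(p.division_sizes) == 16

    @pytest.mark.parametrize("n", range(7, 40))
    def test_near_equal_and_ordered(self, n):
        p = partition_slabs(n)
        sizes = p.division_sizes
        assert sum(sizes) == n
        assert max(sizes) - min(sizes) <= 1
        # larger divisions toward the base
        assert list(sizes) == sorted(sizes, reverse=True)

    def test_small_stack_warns(self):
        with pytest.warns(UserWarning):
            p = partition_slabs(5)
        assert "apex" in p.slab_of_slice

    def test_too_few_rejected(self):
        with pytest.raises(ValueError):
            partition_slabs(3)


class TestSectorOfAngle:
    def test_anterior_is_segment_1(self):
        assert sector_of_angle(0, "basal") == 1
        assert sector_of_angle(29, "basal") == 1
        assert sector_of_angle(331, "basal") == 1

    def test_inferior_is_segment_4(self):
        assert sector_of_angle(180, "basal") == 4
        assert sector_of_angle(180, "mid") == 10
        assert sector_of_angle(180, "apical") == 15

    def test_apex_always_17(self):
        assert all(sector_of_angle(a, "apex") == 17 for a in range(0, 360, 7))

    def test_basal_sector_profile_counts(self):
        counts = np.bincount(
            [sector_of_angle(a, "basal") for a in range(360)], minlength=7
        )
        assert list(counts[1:7]) == [60] * 6

    def test_apical_sector_profile_counts(self):
        counts = np.bincount(
            [sector_of_angle(a, "apical") for a in range(360)], minlength=17
        )
        assert list(counts[13:17]) == [90] * 4


class TestRayDirection:
    def test_cardinal_directions(self):
        for angle, expect in [(0, (-1, 0)), (90, (0, -1)), (180, (1, 0)), (270, (0, 1))]:
            dr, dc = ray_direction(angle)
            assert np.allclose((dr, dc), expect, atol=1e-12)


class TestRadialMaxProfiles:
    def test_uniform_ring(self):
        img = np.zeros((41, 41))
        rows, cols = np.mgrid[0:41, 0:41]
        r = np.hypot(rows - 20, cols - 20)
        img[(r >= 8) & (r <= 14)] = 50.0
        prof = radial_max_profiles(img, (20.0, 20.0))
        assert np.allclose(prof, 50.0)

    def test_single_bright_pixel(self):
        img = np.full((41, 41), 10.0)
        img[8, 20] = 90.0  # straight up from centre = angle 0
        prof = radial_max_profiles(img, (20.0, 20.0))
        assert prof[0] == 90.0
        assert prof[180] == 10.0

    def test_blurred_ring_matches_brute_force(self, rng):
        img = np.zeros((41, 41))
        rows, cols = np.mgrid[0:41, 0:41]
        r = np.hypot(rows - 20, cols - 20)
        img[(r >= 8) & (r <= 14)] = 80.0
        img = gaussian_filter(img + rng.normal(0, 3, img.shape), 1.2)
        prof = radial_max_profiles(img, (20.0, 20.0))
        assert np.allclose(prof, brute_profiles(img, (20.0, 20.0)), atol=1e-9)

    def test_center_outside_rejected(self):
        with pytest.raises(ValueError):
            radial_max_profiles(np.zeros((10, 10)), (20.0, 5.0))


class TestSegmentRepresentativeValues:
    def test_uniform_stack_all_equal(self, uniform_stack):
        table = segment_representative_values(uniform_stack)
        assert np.allclose(table.values, 50.0)

    def test_profile_counts_basal_anterior(self):
        # 2 basal-division slices per division x 2 divisions = 4 basal slices
        stack = ImageStack(np.full((14, 32, 32), 10.0), 2.4, 2.4)
        table = segment_representative_values(stack)
        assert table.n_profiles[0] == 60 * 4
        assert table.n_profiles[16] == 360 * 2  # apex division has 2 slices

    def test_oracle_equivalence_random_phantoms(self, rng):
        for _ in range(10):
            cfg = PhantomConfig(
                matrix_size=48,
                lv_length_mm=24.0,
                endo_radius_mm=float(rng.uniform(9, 12)),
                epi_radius_mm=float(rng.uniform(15, 19)),
                baseline_uptake=float(rng.uniform(50, 95)),
            )
            stack = make_ring_stack(cfg, "spect")
            noisy = np.clip(
                stack.voxels + rng.normal(0, 4, stack.voxels.shape), 0, 100
            )
            stack = stack.copy_with(voxels=noisy)
            center = default_center(stack)
            got = segment_representative_values(stack, center)
            expected = brute_segment_values(stack, center)
            assert np.allclose(got.values, expected, atol=1e-9)

    def test_monotonicity_under_scaling(self, desk_config):
        stack = make_ring_stack(desk_config, "pet")
        t1 = segment_representative_values(stack)
        t2 = segment_representative_values(stack.copy_with(voxels=stack.voxels * 0.5))
        assert np.allclose(t2.values, 0.5 * t1.values, atol=1e-9)

    def test_rotation_by_60_permutes_basal_mid(self, desk_config):
        stack = make_ring_stack(desk_config, "pet")
        # break symmetry: brighten the anterior sector
        c = (stack.size - 1) / 2.0
        rows, cols = np.mgrid[0 : stack.size, 0 : stack.size].astype(float)
        ang = np.degrees(np.arctan2(-(cols - c), -(rows - c))) % 360
        bright = ((ang < 25) | (ang > 335)) & (stack.voxels[0] > 0)
        v = stack.voxels.copy()
        v[:, bright] = np.minimum(v[:, bright] * 1.2, 100.0)
        stack = stack.copy_with(voxels=v)
        t0 = segment_representative_values(stack, (c, c))
        rot = np.stack(
            [rotate(s, 60, reshape=False, order=1, mode="nearest") for s in stack.voxels]
        )
        t60 = segment_representative_values(
            stack.copy_with(voxels=np.clip(rot, 0, 100)), (c, c)
        )
        # counter-clockwise rotation by one sector: basal segment k -> k+1
        for seg in range(1, 7):
            target = seg % 6 + 1
            assert abs(t60.value(target) - t0.value(seg)) <= 1.0

    def test_segment_table_validation(self):
        with pytest.raises(ValueError):
            SegmentTable(values=np.zeros(16), n_profiles=np.ones(16))
        with pytest.raises(ValueError):
            SegmentTable(values=np.full(17, 101.0), n_profiles=np.ones(17))
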