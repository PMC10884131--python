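import numpy as np
import pytest

from mptrans.phantom import (
    AttenuationSpec,
    DefectSpec,
    PhantomConfig,
    apply_attenuation,
    apply_defect,
    generate_patient_pair,
    make_ring_slice,
    make_ring_stack,
    voxel_angles_deg,
)
from mptrans.segment17 import partition_slabs, segment_representative_values


class TestConfigValidation:
    def test_degenerate_radii_rejected(self):
        with pytest.raises(ValueError):
            PhantomConfig(endo_radius_mm=20.0, epi_radius_mm=18.0)

    def test_baseline_bounds(self):
        with pytest.raises(ValueError):
            PhantomConfig(baseline_uptake=0.0)
        with pytest.raises(ValueError):
            PhantomConfig(baseline_uptake=101.0)

    def test_odd_matrix_rejected(self):
        with pytest.raises(ValueError):
            PhantomConfig(matrix_size=65)

    def test_defect_validation(self):
        with pytest.raises(ValueError):
            DefectSpec(segments=(), severity=0.5)
        with pytest.raises(ValueError):
            DefectSpec(segments=(18,), severity=0.5)
        with pytest.raises(ValueError):
            DefectSpec(segments=(4,), severity=1.5)

    def test_attenuation_validation(self):
        with pytest.raises(ValueError):
            AttenuationSpec(min_factor=0.0)
        with pytest.raises(ValueError):
            AttenuationSpec(min_factor=1.2)


class TestMakeRingSlice:
    def test_uniform_mid_slice(self, desk_config):
        img = make_ring_slice(desk_config, 5, "spect")
        inside = img > 0
        assert inside.any()
        assert np.allclose(img[inside], desk_config.baseline_uptake)

    def test_zero_baseline_not_constructible(self):
        with pytest.raises(ValueError):
            PhantomConfig(baseline_uptake=0.0)

    def test_ring_area_matches_brute_force(self, desk_config):
        # independent pixel-count over the annulus inequality
        idx = 5
        img = make_ring_slice(desk_config, idx, "spect")
        n = desk_config.n_slices("spect")
        t = desk_config.taper(idx, n)
        endo, epi = desk_config.endo_radius_mm * t, desk_config.epi_radius_mm * t
        cr, cc = desk_config.center_px("spect")
        px = desk_config.spect_pixel_mm
        count = 0
        for r in range(desk_config.matrix_size):
            for c in range(desk_config.matrix_size):
                d = np.hypot(r - cr, c - cc) * px
                count += endo <= d <= epi
        assert (img > 0).sum() == count

    def test_apex_slice_is_filled_disc(self, desk_config):
        n = desk_config.n_slices("spect")
        part = partition_slabs(n)
        apex_idx = part.slices_in("apex")[0]
        img = make_ring_slice(desk_config, apex_idx, "spect")
        cr, cc = desk_config.center_px("spect")
        assert img[int(round(cr)), int(round(cc))] == desk_config.baseline_uptake

    def test_out_of_range_slice_rejected(self, desk_config):
        with pytest.raises(ValueError):
            make_ring_slice(desk_config, 99, "spect")


class TestApplyDefect:
    def _geometry(self, stack, config, modality):
        return (config.center_px(modality), partition_slabs(stack.n_slices))

    def test_zero_severity_identity(self, desk_config):
        stack = make_ring_stack(desk_config, "pet")
        out = apply_defect(
            stack, self._geometry(stack, desk_config, "pet"),
            DefectSpec(segments=(4,), severity=0.0),
        )
        assert np.array_equal(out.voxels, stack.voxels)

    def test_full_ablation_segment_13(self, desk_config):
        stack = make_ring_stack(desk_config, "pet")
        out = apply_defect(
            stack, self._geometry(stack, desk_config, "pet"),
            DefectSpec(segments=(13,), severity=1.0),
        )
        table = segment_representative_values(out, desk_config.center_px("pet"))
        # boundary rays interpolate across the sector edge at this pixel
        # pitch, so "zero" is approached within a few uptake units
        assert table.value(13) < 5.0
        assert table.value(15) > 75.0

    def test_partial_defect_segment_4(self, desk_config):
        stack = make_ring_stack(desk_config, "pet")
        out = apply_defect(
            stack, self._geometry(stack, desk_config, "pet"),
            DefectSpec(segments=(4,), severity=0.4),
        )
        table = segment_representative_values(out, desk_config.center_px("pet"))
        assert table.value(4) == pytest.approx(48.0, abs=3.0)
        for seg in (1, 2, 7, 13, 17):
            assert table.value(seg) == pytest.approx(80.0, abs=0.5)

    def test_state_filtering(self, desk_config):
        stack = make_ring_stack(desk_config, "pet", state="rest")
        out = apply_defect(
            stack, self._geometry(stack, desk_config, "pet"),
            DefectSpec(segments=(4,), severity=0.9, state="stress"),
        )
        assert np.array_equal(out.voxels, stack.voxels)


class TestApplyAttenuation:
    def test_identity_when_min_factor_1(self, desk_config):
        stack = make_ring_stack(desk_config, "spect")
        out, field = apply_attenuation(stack, AttenuationSpec(min_factor=1.0))
        assert np.allclose(out.voxels, stack.voxels)
        assert np.allclose(field, 1.0)

    def test_field_range_bounds(self, desk_config):
        stack = make_ring_stack(desk_config, "spect")
        spec = AttenuationSpec(min_factor=0.7)
        _, field = apply_attenuation(stack, spec)
        assert field.min() >= spec.min_factor - 1e-12
        assert field.max() <= 1.0 + 1e-12

    def test_inferior_reduced_anterior_unchanged(self, desk_config):
        stack = make_ring_stack(desk_config, "spect")
        center = desk_config.center_px("spect")
        before = segment_representative_values(stack, center)
        out, _ = apply_attenuation(stack, AttenuationSpec(min_factor=0.8), center)
        after = segment_representative_values(out, center)
        # inferior basal/mid (longitudinal multiplier 1) reduced by ~20%
        for seg in (4, 10):
            assert after.value(seg) / before.value(seg) == pytest.approx(0.8, abs=0.03)
        for seg in (1, 7, 13):
            assert after.value(seg) == pytest.approx(before.value(seg), abs=0.5)

    def test_angular_bump_peak_and_support(self):
        spec = AttenuationSpec(min_factor=0.8, peak_direction_deg=180, angular_width_deg=120)
        assert spec.angular_bump(np.array([180.0]))[0] == pytest.approx(1.0)
        assert spec.angular_bump(np.array([120.0]))[0] == pytest.approx(0.0, abs=1e-12)
        assert spec.angular_bump(np.array([0.0]))[0] == 0.0


class TestVoxelAngles:
    def test_cardinal_angles(self):
        ang = voxel_angles_deg(9, (4.0, 4.0))
        assert ang[0, 4] == pytest.approx(0.0)    # above centre -> anterior
        assert ang[4, 0] == pytest.approx(90.0)   # left -> septum
        assert ang[8, 4] == pytest.approx(180.0)  # below -> inferior
        assert ang[4, 8] == pytest.approx(270.0)  # right -> lateral


class TestGeneratePatientPair:
    def test_determinism(self, desk_config):
        import dataclasses

        cfg = dataclasses.replace(desk_config, noise_scale=0.5)
        d = [DefectSpec(segments=(4, 10), severity=0.5)]
        a = AttenuationSpec(min_factor=0.8)
        s1, p1, t1 = generate_patient_pair(cfg, d, a, seed=7)
        s2, p2, t2 = generate_patient_pair(cfg, d, a, seed=7)
        assert np.array_equal(s1.voxels, s2.voxels)
        assert np.array_equal(p1.voxels, p2.voxels)
        assert np.array_equal(t1.true_segment_values, t2.true_segment_values)

    def test_noise_free_pair_differs_only_by_geometry(self, desk_config):
        spect, pet, truth = generate_patient_pair(desk_config, seed=0)
        assert spect.pixel_mm == 2.4 and pet.pixel_mm == 1.6
        ms, mp_ = spect.voxels[spect.voxels > 0], pet.voxels[pet.voxels > 0]
        assert np.allclose(ms, desk_config.baseline_uptake)
        assert np.allclose(mp_, desk_config.baseline_uptake)

    def test_slice_count_ratio(self, desk_config):
        spect, pet, _ = generate_patient_pair(desk_config, seed=0)
        assert pet.n_slices == round(spect.n_slices * 2.4 / 1.6)

    def test_truth_consistency_with_defect(self, desk_config):
        d = [DefectSpec(segments=(4,), severity=0.4)]
        _, _, truth = generate_patient_pair(desk_config, d, None, seed=0)
        expected = np.full(17, 80.0)
        expected[3] = 48.0
        assert np.allclose(truth.true_segment_values, expected)

    def test_truth_field_matches_spect_geometry(self, desk_config):
        spect, _, truth = generate_patient_pair(
            desk_config, None, AttenuationSpec(min_factor=0.8), seed=0
        )
        assert truth.attenuation_field.shape == spect.voxels.shape
        assert truth.defect_map.shape == spect.voxels.shape

    def test_conservation_in_myocardium(self, desk_config):
        # noise/attenuation/defect disabled: every in-myocardium voxel of
        # both modalities equals the baseline
        spect, pet, _ = generate_patient_pair(desk_config, seed=1)
        for stack in (spect, pet):
            inside = stack.voxels > 0
            assert np.allclose(stack.voxels[inside], 80.0)
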