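"""Toy dose engine: radiological depth, field dose, DVH, HU sweep."""

import dataclasses

import numpy as np
import pytest

from lungphan4d import BeamSpec, CTVolume, combine_fields, compute_field_dose, delta_d, dvh_metrics, radiological_depth
from lungphan4d.dose_engine import (
    DoseGrid,
    DVHMetrics,
    ap_pa_plan,
    extract_coronal_plane,
    hu_sweep_experiment,
    hu_to_relative_density,
    resample_volume,
)
from lungphan4d.structures import StructureMask

from _oracles import dvh_percentile_oracle


def _slab(hu_layers, thickness_vox=20, width=21):
    """Stack of uniform HU slabs along the AP axis, 1 mm voxels."""
    ny = thickness_vox * len(hu_layers)
    vals = np.zeros((width, ny, width), dtype=np.float32)
    for i, hu in enumerate(hu_layers):
        vals[:, i * thickness_vox : (i + 1) * thickness_vox, :] = hu
    return CTVolume(vals, spacing=(1, 1, 1), origin=(-(width - 1) / 2, 0.5, -(width - 1) / 2))


class TestRadiologicalDepth:
    def test_water_slab(self):
        vol = _slab([0.0], thickness_vox=120)
        d = radiological_depth(vol, (0.0, 0.0, 0.0), (0, 1, 0), 100.0)
        assert d == pytest.approx(10.0, abs=1e-6)

    def test_lung_slab(self):
        vol = _slab([-625.0], thickness_vox=120)
        d = radiological_depth(vol, (0.0, 0.0, 0.0), (0, 1, 0), 100.0)
        assert d == pytest.approx(3.75, abs=1e-6)

    def test_mixed_slab(self):
        vol = _slab([0.0, -500.0, -500.0], thickness_vox=20)
        d = radiological_depth(vol, (0.0, 0.0, 0.0), (0, 1, 0), 60.0)
        assert d == pytest.approx(2.0 + 4.0 * 0.5, abs=1e-6)

    def test_ray_missing_grid_rejected(self):
        vol = _slab([0.0])
        with pytest.raises(ValueError, match="does not intersect"):
            radiological_depth(vol, (500.0, 0.0, 0.0), (0, 1, 0), 10.0)

    def test_density_ramp_clips_at_zero(self):
        assert hu_to_relative_density(np.array([-2000.0]))[0] == 0.0
        assert hu_to_relative_density(np.array([0.0]))[0] == 1.0


class TestFieldDose:
    def test_water_central_axis_peaks_at_dmax_then_decreases(self):
        vol = _slab([0.0], thickness_vox=200)
        beam = BeamSpec()
        dose = compute_field_dose(vol, beam, isocenter_mm=(0.0, 100.0, 0.0))
        cax = dose.values[10, :, 10]
        depth_mm = vol.axis_coords(1)
        beyond = depth_mm > 15.0
        assert np.all(np.diff(cax[beyond]) < 0)
        # calibration: 1.0 at d_max for 500 MU (up to the aperture profile)
        i_dmax = int(np.argmin(np.abs(depth_mm - 15.0)))
        assert cax[i_dmax] == pytest.approx(1.0, rel=0.02)

    def test_mirror_symmetry(self):
        vol = _slab([0.0, -625.0, 0.0])
        dose = compute_field_dose(vol, BeamSpec(), isocenter_mm=(0.0, 30.0, 0.0))
        assert np.allclose(dose.values, dose.values[::-1, :, :], atol=1e-12)
        assert np.allclose(dose.values, dose.values[:, :, ::-1], atol=1e-12)

    def test_empty_aperture_rejected(self):
        vol = _slab([0.0])
        with pytest.raises(ValueError, match="aperture is empty"):
            compute_field_dose(vol, BeamSpec(), aperture=np.zeros((21, 21)))

    def test_determinism(self):
        vol = _slab([0.0, -625.0])
        a = compute_field_dose(vol, BeamSpec(), isocenter_mm=(0.0, 20.0, 0.0))
        b = compute_field_dose(vol, BeamSpec(), isocenter_mm=(0.0, 20.0, 0.0))
        assert np.array_equal(a.values, b.values)


class TestPlans:
    def test_sum_of_field_with_itself_doubles(self):
        vol = _slab([0.0])
        f = compute_field_dose(vol, BeamSpec(), isocenter_mm=(0.0, 10.0, 0.0))
        assert np.allclose(combine_fields([f, f]).values, 2 * f.values)

    def test_ap_pa_plan_symmetric_and_peaked_at_target(self, noiseless_spec):
        from lungphan4d import MotionModel, render_phase_volume
        from lungphan4d.structures import build_itv_ptv

        still = MotionModel(amplitude_mm=0.0)
        vol = render_phase_volume(noiseless_spec, still, 0)
        _, _, ptv = build_itv_ptv(noiseless_spec, still)
        plan = ap_pa_plan(vol, ptv)
        # symmetric under AP reflection for this AP-symmetric phantom
        assert np.allclose(plan.values, plan.values[:, ::-1, :], rtol=1e-6, atol=1e-9)
        iso_idx = tuple(int(round(i)) for i in vol.world_to_index(noiseless_spec.target_rest_center))
        edge_idx = (iso_idx[0], iso_idx[1], iso_idx[2] + int(round(22.0 / vol.spacing[2])))
        assert plan.values[iso_idx] > plan.values[edge_idx]

    def test_grid_mismatch_rejected(self):
        f1 = DoseGrid(np.ones((3, 3, 3)), spacing=(1, 1, 1), origin=(0, 0, 0))
        f2 = DoseGrid(np.ones((3, 3, 4)), spacing=(1, 1, 1), origin=(0, 0, 0))
        with pytest.raises(ValueError, match="grid mismatch"):
            combine_fields([f1, f2])


class TestHUSweep:
    @pytest.fixture(scope="class")
    def sweep_table(self, noiseless_spec):
        from lungphan4d import MotionModel, gtv_mask_at_phase, render_phase_volume

        still = MotionModel(amplitude_mm=0.0)
        vol = render_phase_volume(noiseless_spec, still, 0)
        gtv = gtv_mask_at_phase(noiseless_spec, still, 0)
        return hu_sweep_experiment(vol, gtv)

    def test_table_shape(self, sweep_table):
        assert len(sweep_table) == 17 * 4

    def test_nominal_override_no_change_upstream(self, sweep_table):
        p1 = sweep_table[sweep_table["point"] == "P1"]["pct_change"].to_numpy()
        assert np.max(np.abs(p1)) < 1e-7  # < 1e-9 relative

    def test_downstream_points_strictly_decreasing(self, sweep_table):
        for point in ("P3", "P4"):
            sub = sweep_table[sweep_table["point"] == point].sort_values("override_hu")
            assert np.all(np.diff(sub["pct_change"].to_numpy()) < 0)

    def test_isocenter_follows_attenuation_sign(self, sweep_table):
        sub = sweep_table[sweep_table["point"] == "P2"].sort_values("override_hu")
        assert np.all(np.diff(sub["pct_change"].to_numpy()) < 0)


class TestDVH:
    def test_uniform_dose_collapses_metrics(self):
        dose = DoseGrid(np.full((5, 5, 5), 2.5), spacing=(1, 1, 1), origin=(0, 0, 0))
        roi = StructureMask(np.ones((5, 5, 5), bool))
        m = dvh_metrics(dose, roi)
        assert m.d_max == m.d_2 == m.d_mean == m.d_95 == m.d_98 == 2.5
        assert all(v == 0.0 for v in delta_d(m, m).values())

    def test_percentiles_match_sort_oracle(self):
        doses = np.arange(1.0, 101.0)
        rng = np.random.default_rng(0)
        arr = rng.permutation(doses).reshape(4, 25, 1)
        dose = DoseGrid(arr, spacing=(1, 1, 1), origin=(0, 0, 0))
        roi = StructureMask(np.ones((4, 25, 1), bool))
        m = dvh_metrics(dose, roi)
        assert m.d_98 == pytest.approx(dvh_percentile_oracle(doses, 98.0))
        assert m.d_2 == pytest.approx(dvh_percentile_oracle(doses, 2.0))
        assert m.d_98 == pytest.approx(2.98)
        assert m.d_2 == pytest.approx(98.02)

    def test_metric_ordering_invariant(self, noiseless_spec):
        from lungphan4d import MotionModel, render_phase_volume
        from lungphan4d.structures import build_itv_ptv

        still = MotionModel(amplitude_mm=0.0)
        vol = render_phase_volume(noiseless_spec, still, 0)
        _, _, ptv = build_itv_ptv(noiseless_spec, still)
        m = dvh_metrics(ap_pa_plan(vol, ptv), ptv)
        assert m.d_max >= m.d_2 >= m.d_95 >= m.d_98
        assert m.d_max >= m.d_mean

    def test_delta_d_sign_convention(self):
        a = DVHMetrics(10.0, 10.0, 10.0, 10.0, 10.0)
        b = DVHMetrics(10.2, 10.2, 10.2, 10.2, 10.2)
        assert delta_d(a, b)["d_max"] == pytest.approx(-2.0)

    def test_zero_denominator_rejected(self):
        z = DVHMetrics(0.0, 0.0, 0.0, 0.0, 0.0)
        with pytest.raises(ValueError, match="zero"):
            delta_d(z, z)


class TestGridUtils:
    def test_resample_preserves_uniform_volume(self):
        vol = _slab([-300.0], thickness_vox=40)
        coarse = resample_volume(vol, (2.0, 2.0, 2.0))
        assert np.allclose(coarse.values, -300.0)
        assert coarse.spacing == (2.0, 2.0, 2.0)

    def test_coronal_plane_extraction(self):
        dose = DoseGrid(np.random.default_rng(0).random((4, 5, 6)), spacing=(1, 1, 1), origin=(0, 0, 0))
        plane = extract_coronal_plane(dose, 2.0)
        assert plane.values.shape == (4, 6)
        assert np.array_equal(plane.values, dose.values[:, 2, :])
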