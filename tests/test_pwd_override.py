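"""Occupancy counting and the phase-weighted density override."""

import numpy as np
import pytest

from lungphan4d import (
    MotionModel,
    PWDParams,
    apply_override,
    build_pwd_dataset,
    compute_occupancy,
    gtv_mask_at_phase,
    pwd_density,
    render_fb_volume,
    si_profile,
    target_center_at_phase,
)
from lungphan4d.structures import StructureMask, build_itv_ptv, union_masks


@pytest.fixture(scope="module")
def geom_masks(geom_spec):
    motion = MotionModel(amplitude_mm=15.0)
    return [gtv_mask_at_phase(geom_spec, motion, p) for p in range(10)]


def brute_force_k(point, amplitude, radius=15.0, rest=(10.0, 0.0, 0.0)):
    """Independent occupancy count: distance of the point to each of the 10
    cosine-sampled sphere centers, strict < r."""
    k = 0
    for p in range(10):
        dz = amplitude * np.cos(2 * np.pi * p / 10)
        c = np.array([rest[0], rest[1], rest[2] + dz])
        if np.linalg.norm(np.asarray(point) - c) < radius:
            k += 1
    return k


class TestOccupancy:
    def test_zero_amplitude_all_or_nothing(self, geom_spec):
        still = MotionModel(amplitude_mm=0.0)
        masks = [gtv_mask_at_phase(geom_spec, still, p) for p in range(10)]
        occ = compute_occupancy(masks)
        assert set(np.unique(occ.counts)) == {0, 10}
        assert np.array_equal(occ.counts == 10, masks[0].mask)

    @pytest.mark.parametrize(
        "point",
        [(10.0, 0.0, 15.0), (10.0, 0.0, 0.0), (10.0, 0.0, -15.0), (10.0, 0.0, 7.0)],
    )
    def test_counts_match_brute_force(self, geom_spec, geom_masks, point):
        occ = compute_occupancy(geom_masks)
        idx = tuple(
            int(round((point[a] - geom_spec.grid_origin()[a]) / geom_spec.grid_spacing[a]))
            for a in range(3)
        )
        assert occ.counts[idx] == brute_force_k(point, 15.0)

    def test_phase0_center_and_rest_center_counts(self, geom_spec, geom_masks):
        """k=5 at the phase-0 sphere center; k=8 at the rest center (the
        two extreme phases sit exactly at distance r and are excluded)."""
        assert brute_force_k((10.0, 0.0, 15.0), 15.0) == 5
        assert brute_force_k((10.0, 0.0, 0.0), 15.0) == 8

    def test_occupancy_conservation(self, geom_masks):
        occ = compute_occupancy(geom_masks)
        assert int(occ.counts.sum()) == sum(m.voxel_count for m in geom_masks)

    def test_itv_is_positive_occupancy(self, geom_masks):
        occ = compute_occupancy(geom_masks)
        itv = union_masks(geom_masks)
        assert np.array_equal(occ.itv_mask().mask, itv.mask)

    def test_grid_mismatch_rejected(self, geom_masks, small_spec):
        other = gtv_mask_at_phase(small_spec, MotionModel(amplitude_mm=0.0), 0)
        with pytest.raises(ValueError, match="grid mismatch"):
            compute_occupancy([geom_masks[0], other])


class TestPWDDensity:
    def test_mixture_endpoints_and_midpoint(self, geom_masks):
        occ = compute_occupancy(geom_masks)
        rho = pwd_density(occ).values
        assert rho[occ.counts == 10].size == 0 or np.all(rho[occ.counts == 10] == -50.0)
        assert np.all(rho[occ.counts == 0] == -625.0)
        assert np.all(rho[occ.counts == 5] == pytest.approx(-337.5))
        k8 = rho[occ.counts == 8]
        assert k8.size > 0 and np.all(k8 == pytest.approx(-165.0))

    def test_monotone_in_k(self, geom_masks):
        occ = compute_occupancy(geom_masks)
        rho = pwd_density(occ).values
        means = [rho[occ.counts == k].mean() for k in range(9) if np.any(occ.counts == k)]
        assert np.all(np.diff(means) > 0)

    def test_itv_mean_identity(self, geom_masks):
        """Occupancy conservation forces the ITV mean of rho_PWD to equal
        rho_lung + (V_GTV/V_ITV)(rho_GTV - rho_lung) exactly."""
        occ = compute_occupancy(geom_masks)
        rho = pwd_density(occ).values
        itv = occ.itv_mask().mask
        v_gtv = np.mean([m.voxel_count for m in geom_masks])
        expected = -625.0 + (v_gtv / itv.sum()) * 575.0
        assert rho[itv].mean() == pytest.approx(expected, abs=1e-9)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError, match="rho_gtv"):
            PWDParams(rho_gtv=-700.0, rho_lung=-625.0)


class TestOverride:
    def test_outside_itv_bit_exact(self, geom_spec, geom_masks):
        motion = MotionModel(amplitude_mm=15.0)
        fb = render_fb_volume(geom_spec, motion)
        pwd, occ = build_pwd_dataset(fb, geom_masks)
        outside = occ.counts == 0
        assert np.array_equal(pwd.values[outside], fb.values[outside].astype(pwd.values.dtype))
        assert np.any(pwd.values[~outside] != fb.values[~outside])

    def test_empty_itv_returns_fb(self, geom_spec):
        still = MotionModel(amplitude_mm=0.0)
        fb = render_fb_volume(geom_spec, still)
        empty = StructureMask(
            np.zeros(fb.values.shape, bool), spacing=fb.spacing, origin=fb.origin
        )
        occ_masks = [gtv_mask_at_phase(geom_spec, still, p) for p in range(10)]
        rho = pwd_density(compute_occupancy(occ_masks))
        out = apply_override(fb, empty, rho)
        assert np.array_equal(out.values, fb.values.astype(out.values.dtype))


class TestProfile:
    def test_noiseless_static_profile_is_top_hat(self, noiseless_spec):
        still = MotionModel(amplitude_mm=0.0)
        gtvs, itv, _ = build_itv_ptv(noiseless_spec, still)
        fb = render_fb_volume(noiseless_spec, still)
        pwd, _ = build_pwd_dataset(fb, gtvs)
        prof = si_profile(pwd, *noiseless_spec.target_rest_center[:2])
        inside = np.abs(prof["si_mm"]) < 14.0
        near_outside = (np.abs(prof["si_mm"]) > 16.0) & (np.abs(prof["si_mm"]) < 60.0)
        assert np.all(prof.loc[inside, "hu"] == -50.0)
        assert np.all(prof.loc[near_outside, "hu"] == -625.0)

    def test_profile_symmetric_with_center_plateau(self, geom_spec, geom_masks):
        """Cosine phase sampling is symmetric under z -> -z, so the PWD
        profile is symmetric about the rest center, with the k=8 plateau
        value -165 HU at the center."""
        occ = compute_occupancy(geom_masks)
        rho = pwd_density(occ)
        prof = si_profile(rho, *geom_spec.target_rest_center[:2])
        hu = prof["hu"].to_numpy()
        z = prof["si_mm"].to_numpy()
        sel = np.abs(z) <= 40
        assert np.allclose(hu[sel], hu[sel][::-1])
        center = int(np.argmin(np.abs(z)))
        assert hu[center] == pytest.approx(-165.0)

    def test_line_outside_grid_rejected(self, geom_spec, geom_masks):
        rho = pwd_density(compute_occupancy(geom_masks))
        with pytest.raises(ValueError, match="outside the grid"):
            si_profile(rho, 500.0, 0.0)
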