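"""SUV quantification: normalization, VOI geometry, max/mean/peak, phantoms."""

import numpy as np
import pytest

from petln.quantify import (
    ScanContext,
    SphereVOI,
    UptakeVolume,
    load_nifti,
    make_phantom,
    peak_sphere_diameter_mm,
    save_nifti,
    suv_max,
    suv_mean,
    suv_normalize,
    suv_peak,
    voi_voxels,
)


def brute_force_voi(volume, voi):
    """Exhaustive per-voxel distance check (independent oracle)."""
    out = set()
    sx, sy, sz = volume.spacing_mm
    cx, cy, cz = voi.center_mm
    r2 = voi.radius_mm ** 2
    for i in range(volume.shape[0]):
        for j in range(volume.shape[1]):
            for k in range(volume.shape[2]):
                if (i * sx - cx) ** 2 + (j * sy - cy) ** 2 + (k * sz - cz) ** 2 <= r2:
                    out.add((i, j, k))
    return out


def brute_force_peak(volume, voi):
    """Double loop over candidate centers and averaging-sphere members."""
    sx, sy, sz = volume.spacing_mm
    r2 = (peak_sphere_diameter_mm() / 2.0) ** 2
    best = -np.inf
    for ci, cj, ck in brute_force_voi(volume, voi):
        vals = []
        for i in range(volume.shape[0]):
            for j in range(volume.shape[1]):
                for k in range(volume.shape[2]):
                    d2 = ((i - ci) * sx) ** 2 + ((j - cj) * sy) ** 2 + ((k - ck) * sz) ** 2
                    if d2 <= r2:
                        vals.append(volume.values[i, j, k])
        best = max(best, float(np.mean(vals)))
    return best


class TestNormalization:
    def test_uniform_concentration_gives_suv_one(self):
        ctx = ScanContext(236.0, 75.0, 56.0)
        conc = ctx.decay_corrected_activity_mbq * 1000.0 / (75.0 * 1000.0)
        vol = UptakeVolume(np.full((4, 4, 3), conc), (1.5, 1.5, 5.0), "kBq_per_ml")
        out = suv_normalize(vol, ctx)
        assert out.units == "suv"
        np.testing.assert_allclose(out.values, 1.0, rtol=1e-12)

    def test_one_half_life_doubles_suv(self):
        vol = UptakeVolume(np.full((2, 2, 2), 5.0), (1.5, 1.5, 5.0), "kBq_per_ml")
        at_zero = suv_normalize(vol, ScanContext(236.0, 75.0, 0.0)).values
        at_t12 = suv_normalize(vol, ScanContext(236.0, 75.0, 109.77)).values
        np.testing.assert_allclose(at_t12, 2.0 * at_zero, rtol=1e-12)

    def test_matches_independent_hand_calculation(self):
        # C = 5 kBq/mL, A = 236 MBq, w = 75 kg, t = 56 min
        expected = 5.0 * 75.0 * 1000.0 / (236.0 * 1000.0 * 2.0 ** (-56.0 / 109.77))
        vol = UptakeVolume(np.full((2, 2, 2), 5.0), (1.5, 1.5, 5.0), "kBq_per_ml")
        out = suv_normalize(vol, ScanContext(236.0, 75.0, 56.0))
        np.testing.assert_allclose(out.values, expected, rtol=1e-12)

    def test_wrong_units_rejected(self):
        vol = UptakeVolume(np.ones((2, 2, 2)), (1.5, 1.5, 5.0), "suv")
        with pytest.raises(ValueError, match="units"):
            suv_normalize(vol, ScanContext(236.0, 75.0, 56.0))

    def test_linear_in_voxel_values(self, rng):
        arr = rng.random((5, 5, 4))
        ctx = ScanContext(200.0, 80.0, 60.0)
        a = suv_normalize(UptakeVolume(arr, (2, 2, 4), "kBq_per_ml"), ctx).values
        b = suv_normalize(UptakeVolume(3.0 * arr, (2, 2, 4), "kBq_per_ml"), ctx).values
        np.testing.assert_allclose(b, 3.0 * a, rtol=1e-12)


class TestVOIGeometry:
    def test_tiny_sphere_selects_single_voxel(self):
        vol = UptakeVolume(np.ones((5, 5, 5)), (1.5, 1.5, 5.0), "suv")
        voi = SphereVOI((3.0, 3.0, 10.0), 1.0)  # centered on voxel (2, 2, 2)
        idx = voi_voxels(vol, voi)
        assert idx.shape == (1, 3)
        assert tuple(idx[0]) == (2, 2, 2)

    def test_enclosing_sphere_selects_all_voxels(self):
        vol = UptakeVolume(np.ones((4, 5, 3)), (1.5, 1.5, 5.0), "suv")
        voi = SphereVOI((2.25, 3.0, 5.0), 1000.0)
        assert len(voi_voxels(vol, voi)) == 4 * 5 * 3

    def test_empty_intersection_raises_with_voi_name(self):
        vol = UptakeVolume(np.ones((5, 5, 5)), (1.5, 1.5, 5.0), "suv")
        with pytest.raises(ValueError, match="far-away"):
            voi_voxels(vol, SphereVOI((500.0, 500.0, 500.0), 2.0, name="far-away"))

    def test_random_spheres_match_brute_force(self, rng):
        vol = UptakeVolume(rng.random((20, 20, 10)), (1.5, 1.5, 5.0), "suv")
        for _ in range(10):
            voi = SphereVOI(
                tuple(rng.uniform([0, 0, 0], [28.5, 28.5, 45.0])),
                float(rng.uniform(4.0, 25.0)),
            )
            try:
                got = set(map(tuple, voi_voxels(vol, voi)))
            except ValueError:
                assert brute_force_voi(vol, voi) == set()
                continue
            assert got == brute_force_voi(vol, voi)


class TestSUVStatistics:
    def test_uniform_volume_all_metrics_equal_value(self):
        vol = make_phantom((10, 10, 6), background=2.5)
        voi = SphereVOI((6.75, 6.75, 12.5), 12.0)
        assert suv_max(vol, voi) == 2.5
        assert suv_mean(vol, voi) == pytest.approx(2.5)
        assert suv_peak(vol, voi) == pytest.approx(2.5)

    def test_single_hot_voxel_sets_suvmax(self):
        arr = np.ones((7, 7, 5))
        arr[3, 3, 2] = 10.0
        vol = UptakeVolume(arr, (1.5, 1.5, 5.0), "suv")
        voi = SphereVOI((4.5, 4.5, 10.0), 12.0)
        assert suv_max(vol, voi) == 10.0

    def test_random_phantoms_match_exhaustive_scan(self, rng):
        for _ in range(5):
            vol = UptakeVolume(rng.random((10, 10, 6)) * 8, (1.5, 1.5, 5.0), "suv")
            voi = SphereVOI(tuple(rng.uniform([3, 3, 5], [10, 10, 20])),
                            float(rng.uniform(6, 14)))
            idx = brute_force_voi(vol, voi)
            vals = [vol.values[i] for i in idx]
            assert suv_max(vol, voi) == pytest.approx(max(vals))
            assert suv_mean(vol, voi) == pytest.approx(float(np.mean(vals)))
            assert suv_peak(vol, voi) == pytest.approx(brute_force_peak(vol, voi))

    def test_peak_bounded_by_averaged_voxels(self, rng):
        # suv_peak averages, so it can never exceed the volume-wide maximum;
        # for a VOI enclosing the whole volume it is bounded by the VOI max
        for _ in range(5):
            vol = UptakeVolume(rng.random((12, 12, 6)) * 10, (1.5, 1.5, 5.0), "suv")
            voi = SphereVOI((8.0, 8.0, 12.0), float(rng.uniform(5, 16)))
            assert suv_peak(vol, voi) <= float(vol.values.max()) + 1e-12
            enclosing = SphereVOI((8.25, 8.25, 12.5), 1000.0)
            assert suv_peak(vol, enclosing) <= suv_max(vol, enclosing) + 1e-12

    def test_axis_permutation_invariance(self, rng):
        arr = rng.random((8, 10, 6)) * 5
        vol = UptakeVolume(arr, (1.5, 2.0, 5.0), "suv")
        voi = SphereVOI((5.0, 8.0, 12.0), 11.0)
        perm = (2, 0, 1)
        vol_p = UptakeVolume(np.transpose(arr, perm),
                             tuple(vol.spacing_mm[a] for a in perm), "suv")
        voi_p = SphereVOI(tuple(voi.center_mm[a] for a in perm), voi.diameter_mm)
        for fn in (suv_max, suv_mean, suv_peak):
            assert fn(vol, voi) == pytest.approx(fn(vol_p, voi_p))


class TestPhantom:
    def test_no_lesions_is_uniform(self):
        vol = make_phantom((6, 6, 4), background=0.5)
        assert np.all(vol.values == 0.5)

    def test_lesion_value_recovered_by_suvmax(self):
        les = SphereVOI((11.25, 11.25, 15.0), 12.0)
        vol = make_phantom((16, 16, 7), background=0.5, lesions=[(les, 8.0)])
        assert suv_max(vol, SphereVOI((11.25, 11.25, 15.0), 25.0)) == 8.0

    def test_same_seed_is_bit_identical(self):
        kw = dict(dims=(10, 10, 5), background=1.0, noise_cv=0.1, seed=7)
        a = make_phantom(**kw)
        b = make_phantom(**kw)
        np.testing.assert_array_equal(a.values, b.values)

    def test_lesion_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            make_phantom((6, 6, 4), lesions=[(SphereVOI((100.0, 0.0, 0.0), 5.0), 3.0)])


def test_nifti_round_trip(tmp_path, rng):
    vol = UptakeVolume(rng.random((6, 6, 4)), (1.5, 1.5, 5.0), "suv")
    path = tmp_path / "vol.nii"
    save_nifti(vol, path)
    back = load_nifti(path, units="suv")
    np.testing.assert_allclose(back.values, vol.values, rtol=1e-6)
    assert back.spacing_mm == pytest.approx(vol.spacing_mm)
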