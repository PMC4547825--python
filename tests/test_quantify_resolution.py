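import numpy as np
import pytest
from scipy.ndimage import gaussian_filter1d

from cryocdi import (DensityVolume, DoseParams, compute_prtf,
                     dose_per_projection, electrons_from_central_speckle,
                     linescan_resolution, make_geometry, mass_density,
                     oversampling_ratios, segment_threshold, simulate_pattern,
                     total_dose)
from cryocdi.fourier_assembly import FourierIntensityVolume
from cryocdi.oss_reconstruction import _cfftn
from cryocdi.quantify_resolution import OversamplingWarning


class TestDose:
    def test_dose_per_projection_reproduces_experiment(self):
        # mu/rho = 9.9 cm^2/g, 4.99e9 ph/um^2, 8 keV -> 6.32e6 Gy
        dp = dose_per_projection(DoseParams(9.9, 4.99e9, 8.0))
        assert dp == pytest.approx(6.32e6, rel=0.01)

    def test_zero_fluence_zero_dose(self):
        assert dose_per_projection(DoseParams(9.9, 0.0, 8.0)) == 0.0

    def test_dose_linear_in_fluence(self):
        d1 = dose_per_projection(DoseParams(9.9, 1e9, 8.0))
        d2 = dose_per_projection(DoseParams(9.9, 2e9, 8.0))
        assert d2 == pytest.approx(2.0 * d1, rel=1e-12)

    def test_total_dose_over_72_projections(self):
        assert total_dose(6.32e6, 72) == pytest.approx(4.55e8, rel=0.01)

    def test_total_dose_identity_and_zero(self):
        assert total_dose(123.0, 1) == 123.0
        assert total_dose(0.0, 50) == 0.0


class TestElectronCount:
    def test_inverts_central_speckle_to_cell_electron_count(self):
        # I(0) = 1.88e7 photons -> N_e ~ 2.08e12 electrons
        n_e = electrons_from_central_speckle(1.88e7, 4.99e9, 55.0 ** 2, 5.29)
        assert n_e == pytest.approx(2.08e12, rel=0.02)

    def test_square_root_law(self):
        n1 = electrons_from_central_speckle(1e6, 4.99e9, 3025.0, 5.29)
        n4 = electrons_from_central_speckle(4e6, 4.99e9, 3025.0, 5.29)
        assert n4 == pytest.approx(2.0 * n1, rel=1e-12)

    def test_forward_inverse_roundtrip(self):
        # simulate_pattern's central pixel and Eq.-(3) inversion are inverses
        geom = make_geometry(8.0, 5.29, 55.0, 64, beamstop_radius_px=0,
                             gap_width_px=0)
        n_e = 3.7e11
        proj = np.zeros((16, 16))
        proj[4:12, 4:12] = n_e / 64
        pat = simulate_pattern(proj, geom)
        recovered = electrons_from_central_speckle(
            pat.counts[32, 32], geom.fluence_per_um2, geom.pixel_area_um2,
            geom.camera_length_m)
        assert recovered == pytest.approx(n_e, rel=1e-10)


class TestMassDensity:
    def test_reproduces_cell_average_density(self):
        assert mass_density(2.08e12, 5.7) == pytest.approx(1.15, rel=0.02)

    def test_halves_when_volume_doubles(self):
        assert mass_density(1e12, 8.0) == pytest.approx(
            mass_density(1e12, 4.0) / 2.0, rel=1e-12)

    def test_zero_electrons_zero_density(self):
        assert mass_density(0.0, 3.0) == 0.0


class TestOversampling:
    def test_support_equal_to_field_of_view_gives_unity(self, production_geometry):
        fov = production_geometry.field_of_view_um
        with pytest.warns(OversamplingWarning):
            ratios = oversampling_ratios(production_geometry, (fov, fov, fov))
        np.testing.assert_allclose(ratios, 1.0, rtol=1e-12)

    def test_production_geometry_four_micron_support(self, production_geometry):
        # lambda*r/(p*D) with D = 4 um -> ~3.7
        ratios = oversampling_ratios(production_geometry, (4.0, 4.0, 4.0))
        assert ratios[0] == pytest.approx(3.7, abs=0.05)

    def test_halving_support_doubles_ratio(self, production_geometry):
        r1 = oversampling_ratios(production_geometry, (4.0, 4.0, 4.0))
        r2 = oversampling_ratios(production_geometry, (2.0, 2.0, 2.0))
        np.testing.assert_allclose(r2, 2.0 * r1, rtol=1e-12)


class TestPRTF:
    def _measured(self, f):
        intens = np.abs(f) ** 2
        return FourierIntensityVolume(intens, np.ones_like(intens),
                                      np.ones(intens.shape, bool))

    def test_identical_members_give_unity(self, uniform_cube_volume):
        f = _cfftn(uniform_cube_volume.values)
        curve = compute_prtf([f, f, f], self._measured(f), 30.0)
        valid = curve.values > 0
        np.testing.assert_allclose(curve.values[valid], 1.0, atol=1e-9)
        assert np.all(curve.values <= 1.0 + 1e-6)
        res, at_edge = curve.resolution_nm(0.5)
        assert at_edge

    def test_random_phase_members_decay_like_inverse_sqrt_k(self):
        # |mean of k unit phasors| ~ 1/sqrt(k)
        rng = np.random.default_rng(8)
        n, k = 16, 20
        modulus = np.ones((n, n, n))
        members = [modulus * np.exp(1j * rng.uniform(-np.pi, np.pi, (n, n, n)))
                   for _ in range(k)]
        measured = FourierIntensityVolume(modulus ** 2, np.ones((n, n, n)),
                                          np.ones((n, n, n), bool))
        curve = compute_prtf(members, measured, 30.0)
        mid = curve.values[4]
        assert mid == pytest.approx(1.0 / np.sqrt(k), rel=0.5)

    def test_stricter_threshold_never_improves_resolution(self):
        rng = np.random.default_rng(9)
        n, k = 16, 5
        modulus = np.ones((n, n, n))
        # phases decohere progressively with |q|
        kk = np.arange(n) - n // 2
        kx, ky, kz = np.meshgrid(kk, kk, kk, indexing="ij")
        sigma = np.sqrt(kx ** 2 + ky ** 2 + kz ** 2) / (n / 4)
        members = [modulus * np.exp(1j * sigma * rng.standard_normal((n, n, n)))
                   for _ in range(k)]
        measured = FourierIntensityVolume(modulus ** 2, np.ones((n, n, n)),
                                          np.ones((n, n, n), bool))
        curve = compute_prtf(members, measured, 30.0)
        res_half, _ = curve.resolution_nm(0.5)
        res_full, _ = curve.resolution_nm(1.0)
        assert res_full >= res_half


class TestLineScan:
    def test_sharp_edge_resolves_to_voxel_floor(self, uniform_cube_volume):
        res = linescan_resolution(uniform_cube_volume, "X")
        assert res <= 2 * uniform_cube_volume.voxel_size_nm

    def test_gaussian_blurred_step_closed_form(self):
        # 10-90% rise of a Gaussian-blurred step is 2.563 sigma
        sigma_nm, voxel_nm = 40.0, 30.0
        profile = np.zeros(128)
        profile[64:] = 1.0
        profile = gaussian_filter1d(profile, sigma_nm / voxel_nm)
        values = np.tile(profile, (128, 128, 1)).transpose(2, 0, 1)
        vol = DensityVolume(np.ascontiguousarray(values), voxel_nm)
        res = linescan_resolution(vol, "X")
        assert res == pytest.approx(2.563 * sigma_nm, rel=0.10)

    def test_no_edge_raises(self):
        flat = DensityVolume(np.full((16, 16, 16), 5.0), 30.0)
        with pytest.raises(ValueError):
            linescan_resolution(flat, "Z")


class TestSegmentation:
    def test_sphere_volume_matches_analytic(self):
        values = np.zeros((128,) * 3)
        z, y, x = np.mgrid[:128, :128, :128]
        values[(z - 64) ** 2 + (y - 64) ** 2 + (x - 64) ** 2 <= 400] = 1.0
        vol = DensityVolume(values, 30.0)
        _, v_um3 = segment_threshold(vol, 0.5)
        assert v_um3 == pytest.approx(4 / 3 * np.pi * 0.6 ** 3, rel=0.05)

    def test_phantom_cell_volume_self_consistent(self):
        # threshold segmentation of a sharp-edged phantom recovers the
        # generator's nominal (analytic) cell volume
        from cryocdi import PhantomSpec, generate_phantom
        spec = PhantomSpec(cell_semi_axes_um=(0.3, 0.2, 0.15),
                           centerline_curvature=0.1)
        vol = generate_phantom(spec, 64, 20.0)
        _, v_um3 = segment_threshold(vol, 0.10)
        assert v_um3 == pytest.approx(spec.cell_volume_um3, rel=0.10)

    def test_invalid_threshold_rejected(self, small_phantom):
        with pytest.raises(ValueError):
            segment_threshold(small_phantom, 0.0)

    def test_empty_volume_rejected(self):
        with pytest.raises(ValueError):
            segment_threshold(DensityVolume(np.zeros((8, 8, 8)), 30.0), 0.1)
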