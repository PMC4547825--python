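import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cryocdi import DensityVolume, OSSConfig, PhantomSpec, generate_phantom
from cryocdi.fourier_assembly import FourierIntensityVolume
from cryocdi.oss_reconstruction import (SupportMask, _cfftn, _cifftn,
                                        _modulus_project, align_volumes,
                                        cubic_support, derive_support,
                                        oss_step, rfactor, run_ensemble,
                                        two_stage_reconstruct)


def _full_intensity(values):
    intens = np.abs(_cfftn(values)) ** 2
    return FourierIntensityVolume(intens, np.ones_like(intens),
                                  np.ones(intens.shape, bool))


@pytest.fixture(scope="module")
def tiny_object():
    spec = PhantomSpec(cell_semi_axes_um=(0.06, 0.05, 0.04),
                       centerline_curvature=0.0, edge_sigma_um=0.03)
    return generate_phantom(spec, 16, 30.0)


class TestRFactor:
    def test_perfect_agreement(self):
        m = np.abs(np.random.default_rng(0).random((5, 5, 5))) + 0.1
        r, gamma = rfactor(m, m, np.ones(m.shape, bool))
        assert r == pytest.approx(0.0, abs=1e-12)
        assert gamma == pytest.approx(1.0, rel=1e-12)

    def test_global_scale_absorbed(self):
        m = np.abs(np.random.default_rng(1).random((5, 5, 5))) + 0.1
        r, gamma = rfactor(m, 2.0 * m, np.ones(m.shape, bool))
        assert r == pytest.approx(0.0, abs=1e-12)
        assert gamma == pytest.approx(0.5, rel=1e-12)

    def test_two_voxel_hand_example(self):
        # exp {4, 2}, calc {2, 2}: gamma = 12/8 = 1.5, R = (1 + 1)/6 = 1/3
        exp = np.array([4.0, 2.0])
        calc = np.array([2.0, 2.0])
        r, gamma = rfactor(exp, calc, np.ones(2, bool))
        assert gamma == pytest.approx(1.5, rel=1e-12)
        assert r == pytest.approx(1.0 / 3.0, rel=1e-12)

    def test_all_zero_experimental_modulus_rejected(self):
        with pytest.raises(ValueError):
            rfactor(np.zeros((3, 3, 3)), np.ones((3, 3, 3)),
                    np.ones((3, 3, 3), bool))

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.floats(0.01, 100.0))
    def test_invariant_to_experimental_density_scale(self, scale):
        rng = np.random.default_rng(3)
        exp = rng.random((4, 4, 4)) + 0.1
        calc = rng.random((4, 4, 4)) + 0.1
        mask = np.ones((4, 4, 4), bool)
        r1, _ = rfactor(exp, calc, mask)
        r2, _ = rfactor(exp, scale * calc, mask)
        assert r1 == pytest.approx(r2, rel=1e-9)


class TestProjections:
    def test_modulus_projection_idempotent(self):
        rng = np.random.default_rng(4)
        f = rng.standard_normal((8, 8, 8)) + 1j * rng.standard_normal((8, 8, 8))
        modulus = np.abs(rng.standard_normal((8, 8, 8)))
        known = rng.random((8, 8, 8)) < 0.7
        once = _modulus_project(f, modulus, known)
        twice = _modulus_project(once, modulus, known)
        np.testing.assert_allclose(once, twice, rtol=1e-12, atol=1e-12)

    def test_support_and_positivity_projections_idempotent(self):
        rng = np.random.default_rng(5)
        rho = rng.standard_normal((8, 8, 8))
        support = cubic_support(8).mask
        proj = np.where(support, np.clip(rho, 0.0, None), 0.0)
        np.testing.assert_array_equal(
            proj, np.where(support, np.clip(proj, 0.0, None), 0.0))


class TestOSSStep:
    def test_true_solution_is_fixed_point(self, tiny_object):
        intens = _full_intensity(tiny_object.values)
        modulus = np.sqrt(intens.intensities)
        support = SupportMask(tiny_object.values > 0)
        out = oss_step(tiny_object.values, modulus, intens.known_mask,
                       support.mask, alpha=np.inf)
        scale = np.abs(tiny_object.values).max()
        np.testing.assert_allclose(out, tiny_object.values,
                                   atol=1e-6 * scale)

    def test_infinite_alpha_reduces_to_plain_hio(self, tiny_object):
        intens = _full_intensity(tiny_object.values)
        modulus = np.sqrt(intens.intensities)
        known = intens.known_mask
        support = cubic_support(16).mask
        rng = np.random.default_rng(6)
        rho = rng.standard_normal((16, 16, 16))
        beta = 0.9
        stepped = oss_step(rho, modulus, known, support, alpha=np.inf, beta=beta)
        # manual HIO with positivity for reference
        rho_proj = _cifftn(_modulus_project(_cfftn(rho), modulus, known)).real
        keep = support & (rho_proj >= 0)
        manual = np.where(keep, rho_proj, rho - beta * rho_proj)
        np.testing.assert_allclose(stepped, manual, atol=1e-6)

    def test_seeded_run_reduces_modulus_residual(self, tiny_object):
        # the R_rec of a converged run falls far below the starting value
        intens = _full_intensity(tiny_object.values)
        cfg = OSSConfig(n_iterations=200, n_seeds=1, keep_best=1, rng_seed=0)
        results, _ = run_ensemble(intens, cubic_support(16), cfg, 30.0)
        trace = results[0].r_trace
        assert trace[-1] < 0.1 * trace[0]


class TestEnsemble:
    def test_single_seed_average_is_that_reconstruction(self, tiny_object):
        intens = _full_intensity(tiny_object.values)
        cfg = OSSConfig(n_iterations=100, n_seeds=1, keep_best=1, rng_seed=2)
        results, average = run_ensemble(intens, cubic_support(16), cfg, 30.0)
        np.testing.assert_array_equal(average.values, results[0].density.values)

    def test_deterministic_for_fixed_seed(self, tiny_object):
        intens = _full_intensity(tiny_object.values)
        cfg = OSSConfig(n_iterations=100, n_seeds=2, keep_best=2, rng_seed=9)
        _, avg1 = run_ensemble(intens, cubic_support(16), cfg, 30.0)
        _, avg2 = run_ensemble(intens, cubic_support(16), cfg, 30.0)
        np.testing.assert_array_equal(avg1.values, avg2.values)

    def test_average_is_mean_of_aligned_best_members(self, tiny_object):
        intens = _full_intensity(tiny_object.values)
        cfg = OSSConfig(n_iterations=100, n_seeds=3, keep_best=3, rng_seed=11)
        results, average = run_ensemble(intens, cubic_support(16), cfg, 30.0)
        ref = results[0].density.values
        stack = [ref] + [align_volumes(ref, r.density.values)
                         for r in results[1:]]
        np.testing.assert_allclose(average.values,
                                   np.clip(np.mean(stack, axis=0), 0.0, None))

    def test_final_r_equals_last_trace_entry(self, tiny_object):
        intens = _full_intensity(tiny_object.values)
        cfg = OSSConfig(n_iterations=100, n_seeds=1, keep_best=1, rng_seed=3)
        results, _ = run_ensemble(intens, cubic_support(16), cfg, 30.0)
        assert results[0].final_r == results[0].r_trace[-1]

    def test_small_noiseless_recovery(self, tiny_object):
        intens = _full_intensity(tiny_object.values)
        cfg = OSSConfig(n_iterations=200, n_seeds=3, keep_best=2, rng_seed=1)
        _, average = run_ensemble(intens, cubic_support(16), cfg, 30.0)
        aligned = align_volumes(tiny_object.values, average.values)
        support = tiny_object.values > 0
        r = np.corrcoef(tiny_object.values[support], aligned[support])[0, 1]
        assert r > 0.9


class TestSupport:
    def test_uniform_cube_threshold_recovers_cube(self, uniform_cube_volume):
        mask = derive_support(uniform_cube_volume, 0.5, dilation=0).mask
        np.testing.assert_array_equal(mask, uniform_cube_volume.values > 0)

    def test_dilation_grows_sphere_radius(self):
        values = np.zeros((48, 48, 48))
        z, y, x = np.mgrid[:48, :48, :48]
        values[(z - 24) ** 2 + (y - 24) ** 2 + (x - 24) ** 2 <= 100] = 1.0
        mask = derive_support(DensityVolume(values, 30.0), 0.5, dilation=2).mask
        r_eq = (3 * mask.sum() / (4 * np.pi)) ** (1 / 3)
        assert r_eq == pytest.approx(12.0, abs=1.0)

    def test_degenerate_threshold(self):
        rng = np.random.default_rng(12)
        noisy = DensityVolume(rng.random((16, 16, 16)), 30.0)
        mask = derive_support(noisy, 0.999, dilation=0).mask
        assert mask.sum() <= 3  # near-singleton

    def test_threshold_out_of_range_rejected(self, uniform_cube_volume):
        with pytest.raises(ValueError):
            derive_support(uniform_cube_volume, 1.5)

    def test_support_fraction_cap(self):
        with pytest.raises(ValueError):
            SupportMask(np.ones((8, 8, 8), bool))


class TestTwoStage:
    def test_stage2_support_contained_in_stage1_cube(self, tiny_object):
        intens = _full_intensity(tiny_object.values)
        cfg = OSSConfig(n_iterations=100, n_seeds=2, keep_best=2, rng_seed=4)
        result = two_stage_reconstruct(intens, cfg, 30.0, support_dilation=1)
        from scipy.ndimage import binary_dilation
        cube = cubic_support(16).mask
        dilated_cube = binary_dilation(cube, iterations=1)
        assert np.all(dilated_cube[result.support.mask])
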