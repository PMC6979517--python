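"""Forward-model tests: PSF construction, circular blur, adjoint, degradation."""

import numpy as np
import pytest

import vancittert as vc
from vancittert.imaging import SCENARIO_TABLE, psf_from_array

from conftest import ALL_PSFS, brute_force_circular_convolve, make_named_psf


def delta_kernel(size: int = 5) -> np.ndarray:
    k = np.zeros((size, size))
    k[size // 2, size // 2] = 1.0
    return k


class TestMakePsf:
    def test_uniform9_is_flat(self):
        psf = vc.make_psf("uniform9")
        assert psf.shape == (9, 9)
        assert np.allclose(psf, 1.0 / 81.0)

    def test_separable1461_binomial(self):
        psf = vc.make_psf("separable1461")
        row = np.array([1, 4, 6, 4, 1], dtype=float)
        assert np.allclose(psf, np.outer(row, row) / 256.0)
        assert psf.sum() == pytest.approx(1.0, abs=1e-15)

    def test_cauchy15_profile(self):
        psf = vc.make_psf("cauchy15")
        assert psf.shape == (15, 15)
        # pre-normalisation centre is 1 and corner 1/99; ratios survive
        # the unit-sum normalisation
        assert psf[7, 7] / psf[0, 0] == pytest.approx(99.0, rel=1e-12)

    def test_gaussian_requires_positive_std(self):
        with pytest.raises(ValueError, match="std"):
            vc.make_psf("gaussian", std=0.0)

    def test_unknown_kind(self):
        with pytest.raises(ValueError, match="unknown PSF kind"):
            vc.make_psf("motion_blur")

    @pytest.mark.parametrize("name", sorted(ALL_PSFS))
    def test_normalised_to_unit_sum(self, name):
        psf = make_named_psf(name)
        assert abs(psf.sum() - 1.0) < 1e-12
        assert np.all(psf >= 0)

    def test_even_support_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            psf_from_array(np.ones((4, 4)))


class TestConvolve:
    def test_delta_kernel_is_identity(self, rng):
        img = rng.uniform(0, 255, (16, 16))
        assert np.allclose(vc.convolve(img, delta_kernel()), img, atol=1e-10)

    def test_constant_image_preserved(self):
        img = np.full((32, 32), 42.0)
        for name in ALL_PSFS:
            out = vc.convolve(img, make_named_psf(name))
            assert np.allclose(out, 42.0, atol=1e-10)

    def test_matches_brute_force_spatial_oracle(self, rng):
        img = rng.uniform(0, 255, (16, 16))
        psf = vc.make_psf("uniform9")
        expected = brute_force_circular_convolve(img, psf)
        np.testing.assert_allclose(vc.convolve(img, psf), expected, rtol=1e-8, atol=1e-8)

    def test_mean_preserved(self, rng):
        img = rng.uniform(0, 255, (32, 32))
        for name in ALL_PSFS:
            out = vc.convolve(img, make_named_psf(name))
            assert out.mean() == pytest.approx(img.mean(), rel=1e-10)

    def test_kernel_larger_than_image_errors(self, rng):
        with pytest.raises(ValueError, match="does not fit"):
            vc.convolve(rng.uniform(0, 255, (8, 8)), vc.make_psf("uniform9"))

    def test_linear_in_image(self, rng):
        a = rng.uniform(0, 255, (16, 16))
        b = rng.uniform(0, 255, (16, 16))
        psf = vc.make_psf("separable1461")
        lhs = vc.convolve(2.0 * a + 0.5 * b, psf)
        rhs = 2.0 * vc.convolve(a, psf) + 0.5 * vc.convolve(b, psf)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)


class TestAdjoint:
    def test_symmetric_kernel_self_adjoint(self, rng):
        img = rng.uniform(0, 255, (16, 16))
        psf = vc.make_psf("uniform9")
        np.testing.assert_allclose(
            vc.adjoint_convolve(img, psf), vc.convolve(img, psf), atol=1e-10
        )

    def test_adjoint_identity_random_asymmetric_kernel(self, rng):
        psf = psf_from_array(rng.uniform(0.01, 1.0, (3, 3)))
        a = rng.standard_normal((8, 8))
        b = rng.standard_normal((8, 8))
        lhs = np.vdot(vc.convolve(a, psf), b)
        rhs = np.vdot(a, vc.adjoint_convolve(b, psf))
        scale = np.linalg.norm(a) * np.linalg.norm(b)
        assert abs(lhs - rhs) / scale < 1e-10


class TestTransferFunction:
    def test_delta_kernel_flat_spectrum(self):
        tf = vc.transfer_function(delta_kernel(), (12, 12))
        np.testing.assert_allclose(tf, 1.0, atol=1e-12)

    @pytest.mark.parametrize("name", sorted(ALL_PSFS))
    def test_dc_value_is_one(self, name):
        tf = vc.transfer_function(make_named_psf(name), (32, 32))
        assert tf[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_pointwise_multiplication_equals_convolve(self, rng):
        img = rng.uniform(0, 255, (16, 16))
        psf = vc.make_psf("uniform9")
        tf = vc.transfer_function(psf, img.shape)
        via_spectrum = np.real(np.fft.ifft2(np.fft.fft2(img) * tf))
        np.testing.assert_allclose(via_spectrum, vc.convolve(img, psf), atol=1e-10)

    def test_shape_smaller_than_kernel_errors(self):
        with pytest.raises(ValueError, match="does not fit"):
            vc.transfer_function(vc.make_psf("uniform9"), (8, 8))


class TestDegrade:
    def test_zero_variance_delta_kernel_exact(self, rng):
        img = rng.uniform(0, 255, (16, 16))
        np.testing.assert_allclose(vc.degrade(img, delta_kernel(), 0.0, seed=0), img, atol=1e-10)

    def test_noise_variance_calibrated(self):
        truth = vc.synth_image(vc.FixtureSpec(size=(512, 512), seed=2))
        psf = vc.make_psf("separable1461")
        obs = vc.degrade(truth, psf, 49.0, seed=5)
        noise = obs - vc.convolve(truth, psf)
        assert np.var(noise) == pytest.approx(49.0, rel=0.03)

    def test_seed_reproducibility_bit_identical(self, blobs64):
        psf = vc.make_psf("cauchy15")
        a = vc.degrade(blobs64, psf, 4.0, seed=9)
        b = vc.degrade(blobs64, psf, 4.0, seed=9)
        assert np.array_equal(a, b)

    def test_different_seeds_uncorrelated(self):
        truth = np.zeros((256, 256))
        psf = delta_kernel()
        n1 = vc.degrade(truth, psf, 25.0, seed=1).ravel()
        n2 = vc.degrade(truth, psf, 25.0, seed=2).ravel()
        assert abs(np.corrcoef(n1, n2)[0, 1]) < 0.05

    def test_negative_variance_rejected(self, blobs64):
        with pytest.raises(ValueError, match=">= 0"):
            vc.degrade(blobs64, delta_kernel(), -1.0, seed=0)


class TestScenarios:
    def test_table_mapping(self):
        assert vc.build_scenario(1).psf_kind == "cauchy15"
        assert vc.build_scenario(1).noise_variance == 2.0
        assert vc.build_scenario(2).noise_variance == 8.0
        assert vc.build_scenario(4).psf_kind == "separable1461"
        assert vc.build_scenario(4).noise_variance == 49.0
        scn5 = vc.build_scenario(5)
        assert scn5.psf_kind == "gaussian" and scn5.psf_params["std"] == 1.6
        assert scn5.noise_variance == 4.0
        assert vc.build_scenario(6).psf_params["std"] == 0.4
        assert vc.build_scenario(6).noise_variance == 64.0

    def test_scenario3_variance_configurable(self):
        assert vc.build_scenario(3).noise_variance == pytest.approx(0.3)
        assert vc.build_scenario(3, scenario3_noise_variance=0.5).noise_variance == 0.5

    def test_out_of_range_index(self):
        for bad in (0, 7):
            with pytest.raises(ValueError):
                vc.build_scenario(bad)

    def test_scenario_psf_buildable(self):
        for i in SCENARIO_TABLE:
            psf = vc.build_scenario(i).make_psf()
            assert abs(psf.sum() - 1.0) < 1e-12
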