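"""Angular densities, their exponential moments, and the 1-D marginal."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import integrate, special

import biasfront as bf
from biasfront.errors import ValidationError

TWO_PI = 2 * math.pi


def brute_mgf(bias, s):
    """Independent oracle: direct quadrature of e^{s cos th} Phi(th)."""
    val, _ = integrate.quad(
        lambda th: math.exp(s * math.cos(th)) * bf.angular_pdf(bias, th),
        -math.pi, math.pi, points=[0.0], limit=200,
    )
    return val


class TestRadialKernel:
    def test_invariants_enforced(self):
        with pytest.raises(ValidationError):
            bf.RadialKernel(r=(1.0, 0.5), p=(0.5, 0.5))  # not increasing
        with pytest.raises(ValidationError):
            bf.RadialKernel(r=(-1.0, 2.0), p=(0.5, 0.5))
        with pytest.raises(ValidationError):
            bf.RadialKernel(r=(1.0, 2.0), p=(0.6, 0.6))  # sum != 1
        with pytest.raises(ValidationError):
            bf.RadialKernel(r=(), p=())

    def test_csv_round_trip(self, herder_kernel, tmp_path):
        path = tmp_path / "kernel.csv"
        herder_kernel.to_csv(path)
        back = bf.RadialKernel.from_csv(path)
        assert back == herder_kernel


class TestAngularPdf:
    @pytest.mark.parametrize("variant,p", [
        ("model1", 0.5), ("model2", 0.5), ("model3", 0.5), ("isotropic", 0.5),
    ])
    def test_isotropic_collapse_pointwise(self, variant, p):
        theta = np.linspace(-math.pi, math.pi, 41)
        np.testing.assert_allclose(
            bf.angular_pdf(bf.AngularBias(variant, p), theta), 1 / TWO_PI, atol=1e-12
        )

    def test_model2_max_bias_peak(self):
        assert bf.angular_pdf(bf.AngularBias("model2", 1.0), 0.0) == pytest.approx(1 / math.pi)

    def test_model3_amplitude_closed_form(self):
        # p = 0.55 -> q = 1: peak value is A = 1 / (sqrt(pi) erf(pi))
        bias = bf.AngularBias("model3", 0.55)
        expected = 1.0 / (math.sqrt(math.pi) * special.erf(math.pi))
        assert bf.angular_pdf(bias, 0.0) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("variant,p", [
        ("model1", 0.8), ("model2", 0.97), ("model3", 0.53), ("model3", 1.5),
        ("isotropic", 0.5),
    ])
    def test_normalized_even_nonnegative(self, variant, p):
        bias = bf.AngularBias(variant, p)
        theta = np.linspace(0, math.pi, 300)
        left = bf.angular_pdf(bias, -theta)
        right = bf.angular_pdf(bias, theta)
        np.testing.assert_array_equal(left, right)
        assert np.all(right >= 0)
        total, _ = integrate.quad(lambda th: bf.angular_pdf(bias, th),
                                  -math.pi, math.pi, points=[0.0], limit=200)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_rejections(self):
        with pytest.raises(ValidationError):
            bf.angular_pdf(bf.AngularBias("model2", 0.9), 4.0)  # out of range theta
        with pytest.raises(ValidationError):
            bf.AngularBias("model2", 1.2)  # density would go negative
        with pytest.raises(ValidationError):
            bf.AngularBias("model1", 0.4)  # backward bias undefined
        with pytest.raises(ValidationError):
            bf.AngularBias("model3", math.inf)  # must use the delta variant
        with pytest.raises(ValidationError):
            bf.angular_pdf(bf.AngularBias("delta"), 0.0)  # point measure


class TestAngularMgf:
    def test_at_zero_is_exactly_one(self):
        for bias in [bf.AngularBias("model1", 0.7), bf.AngularBias("model3", 2.0),
                     bf.AngularBias("delta"), bf.AngularBias("isotropic")]:
            assert bf.angular_mgf(bias, 0.0) == 1.0

    def test_isotropic_value_is_bessel(self):
        bias = bf.AngularBias("isotropic")
        assert bf.angular_mgf(bias, 1.0) == pytest.approx(brute_mgf(bias, 1.0), rel=1e-10)
        assert bf.angular_mgf(bias, 1.0) == pytest.approx(1.2660658777520084, rel=1e-12)

    def test_delta_is_pure_exponential(self):
        assert bf.angular_mgf(bf.AngularBias("delta"), 2.0) == pytest.approx(math.e**2)
        assert bf.angular_log_mgf(bf.AngularBias("delta"), 4321.0) == 4321.0

    @given(p=st.floats(0.5, 1.0), s=st.floats(0.0, 50.0))
    def test_model1_closed_form_matches_quadrature(self, p, s):
        bias = bf.AngularBias("model1", p)
        assert bf.angular_mgf(bias, s) == pytest.approx(brute_mgf(bias, s), rel=1e-8)

    @given(p=st.floats(0.5, 1.0), s=st.floats(0.0, 50.0))
    def test_model2_closed_form_matches_quadrature(self, p, s):
        bias = bf.AngularBias("model2", p)
        assert bf.angular_mgf(bias, s) == pytest.approx(brute_mgf(bias, s), rel=1e-8)

    def test_models_agree_at_half(self):
        for s in (0.3, 2.0, 17.0):
            vals = [bf.angular_mgf(bf.AngularBias(v, 0.5), s)
                    for v in ("model1", "model2", "model3", "isotropic")]
            np.testing.assert_allclose(vals, vals[0], rtol=1e-10)

    @pytest.mark.parametrize("variant", ["model1", "model2", "model3"])
    def test_monotone_in_bias(self, variant):
        s = 3.0
        ps = [0.5, 0.6, 0.75, 0.9, 1.0] if variant != "model3" else [0.5, 0.6, 1.0, 2.0]
        vals = [bf.angular_mgf(bf.AngularBias(variant, p), s) for p in ps]
        assert np.all(np.diff(vals) >= 0)

    def test_bounded_by_extreme_directions(self):
        for bias in [bf.AngularBias("model1", 0.9), bf.AngularBias("model3", 0.7)]:
            for s in (0.5, 5.0, 40.0):
                b = bf.angular_mgf(bias, s)
                assert math.exp(-s) <= b <= math.exp(s)

    def test_model3_saturates_to_delta(self):
        # p = 5 (q = 90) concentrates essentially all mass at theta = 0
        bias = bf.AngularBias("model3", 5.0)
        for s in (0.1, 1.0, 5.0, 20.0):
            ratio = math.exp(bf.angular_log_mgf(bias, s) - s)  # B(s) / e^s
            assert ratio == pytest.approx(1.0, rel=1e-3)

    def test_negative_s_rejected(self):
        with pytest.raises(ValidationError):
            bf.angular_mgf(bf.AngularBias("isotropic"), -0.1)


class TestMarginal:
    def test_single_bin_delta_lands_forward(self):
        kern = bf.RadialKernel(r=(10.0,), p=(1.0,))
        marg = bf.marginal_forward_kernel(kern, bf.AngularBias("delta"), 0.5)
        assert marg.weights.sum() == pytest.approx(1.0, abs=1e-10)
        assert list(marg.cell_offsets) == [20]

    def test_single_bin_isotropic_is_symmetric(self):
        kern = bf.RadialKernel(r=(10.0,), p=(1.0,))
        marg = bf.marginal_forward_kernel(kern, bf.AngularBias("isotropic"), 0.1)
        mean = np.sum(marg.cell_offsets * marg.grid_spacing * marg.weights)
        assert marg.weights.sum() == pytest.approx(1.0, abs=1e-10)
        assert abs(mean) < 0.05  # within discretization tolerance
        assert np.all(np.abs(marg.cell_offsets) * marg.grid_spacing <= 10.0 + 0.1)

    def test_forward_mass_matches_monte_carlo(self, herder_kernel):
        """Model-1 forward fraction of the projected kernel equals p."""
        bias = bf.AngularBias("model1", 0.9)
        marg = bf.marginal_forward_kernel(herder_kernel, bias, 0.25)
        rng = np.random.default_rng(20240917)
        n = 1_000_000
        r = rng.choice(herder_kernel.distances, size=n, p=herder_kernel.probabilities)
        forward = rng.random(n) < 0.9
        theta = np.where(forward,
                         rng.uniform(-np.pi / 2, np.pi / 2, n),
                         np.pi / 2 + rng.uniform(0, np.pi, n))
        mc_forward = np.mean(r * np.cos(theta) > 0)
        assert marg.forward_mass == pytest.approx(0.9, abs=1e-3)
        assert marg.forward_mass == pytest.approx(mc_forward, abs=2e-3)

    def test_support_bounded_by_rmax(self, farmer_kernel):
        marg = bf.marginal_forward_kernel(farmer_kernel, bf.AngularBias("model2", 0.8), 0.5)
        assert np.max(np.abs(marg.cell_offsets)) * 0.5 <= farmer_kernel.r_max + 0.5

    def test_too_coarse_grid_rejected(self, herder_kernel):
        with pytest.raises(ValidationError):
            bf.marginal_forward_kernel(herder_kernel, bf.AngularBias("isotropic"), 1.0)


class TestFixture:
    def test_single_bin(self):
        kern = bf.random_kernel_fixture(seed=1, n_bins=1, max_distance=50)
        assert kern.n_bins == 1 and kern.p == (1.0,)

    def test_reproducible_and_valid(self):
        a = bf.random_kernel_fixture(seed=2, n_bins=5, max_distance=100)
        b = bf.random_kernel_fixture(seed=2, n_bins=5, max_distance=100)
        assert a == b
        assert np.all(np.diff(a.distances) > 0)
        assert a.probabilities.sum() == pytest.approx(1.0, abs=1e-12)

    @given(seed=st.integers(0, 1000), n_bins=st.integers(1, 8))
    def test_any_fixture_normalizes_mgf(self, seed, n_bins):
        kern = bf.random_kernel_fixture(seed, n_bins)
        assert kern.probabilities.sum() == pytest.approx(1.0, abs=1e-12)
        assert bf.angular_mgf(bf.AngularBias("model2", 0.8), 0.0) == 1.0
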