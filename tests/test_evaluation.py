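"""Information-rate estimation, phase scrambling, Lp filter statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcgsm import (
    MCGSMParams,
    combine_rates,
    conditional_cross_entropy,
    cross_mir,
    fit_lp,
    lp_pairs,
    marginal_entropy,
    phase_scramble,
    filter_pair_statistic,
    scale_invariance_profile,
)
from mcgsm.evaluation import _dog_kernel


class TestMarginalEntropy:
    def test_gaussian_closed_form(self):
        x = np.random.default_rng(0).standard_normal(100_000)
        expected = 0.5 * np.log2(2 * np.pi * np.e)
        assert marginal_entropy(x) == pytest.approx(expected, abs=0.02)

    def test_uniform_closed_form(self):
        x = np.random.default_rng(1).random(100_000)
        assert marginal_entropy(x) == pytest.approx(0.0, abs=0.02)

    def test_scaling_shifts_by_log(self):
        x = np.random.default_rng(2).standard_normal(50_000)
        assert marginal_entropy(8.0 * x) - marginal_entropy(x) == pytest.approx(3.0, abs=0.01)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            marginal_entropy(np.ones(1000))


class TestCombineRates:
    def test_weight_arithmetic(self):
        assert combine_rates(4.0, [0.0]) == pytest.approx(1.0)
        assert combine_rates(8.0, [2.0, 4.0]) == pytest.approx(2.75)
        assert combine_rates(5.0, []) == pytest.approx(5.0)

    @given(L=st.integers(0, 10), h=st.floats(-5, 5))
    @settings(deadline=None, max_examples=30)
    def test_convex_weights_sum_to_one(self, L, h):
        # equal per-scale rates pass through unchanged for any depth
        assert combine_rates(h, [h] * L) == pytest.approx(h, abs=1e-12)


class TestConditionalCrossEntropy:
    def _gaussian_pairs(self, rho, n, rng):
        y = rng.standard_normal((n, 1))
        x = rho * y + np.sqrt(1 - rho**2) * rng.standard_normal((n, 1))
        return y, x

    def test_true_model_attains_conditional_entropy(self):
        rng = np.random.default_rng(3)
        rho = 0.8
        Y, X = self._gaussian_pairs(rho, 50_000, rng)
        model = MCGSMParams(
            K=np.ones((1, 1, 1)), alphas=np.ones((1, 1)),
            A=np.full((1, 1, 1), rho), Sigma=np.full((1, 1, 1), 1 - rho**2),
        )
        est, sem = conditional_cross_entropy(model, Y, X)
        expected = 0.5 * np.log2(2 * np.pi * np.e * (1 - rho**2))
        assert abs(est - expected) < 3 * sem + 1e-9

    def test_wrong_model_never_beats_truth(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            rho = rng.uniform(-0.9, 0.9)
            Y, X = self._gaussian_pairs(rho, 5_000, rng)
            truth = MCGSMParams(
                K=np.ones((1, 1, 1)), alphas=np.ones((1, 1)),
                A=np.full((1, 1, 1), rho), Sigma=np.full((1, 1, 1), 1 - rho**2),
            )
            wrong = MCGSMParams(
                K=np.ones((1, 1, 1)), alphas=np.ones((1, 1)),
                A=np.full((1, 1, 1), rng.uniform(-1, 1)),
                Sigma=np.full((1, 1, 1), np.exp(rng.uniform(-1, 1))),
            )
            h_true, sem = conditional_cross_entropy(truth, Y, X)
            h_wrong, _ = conditional_cross_entropy(wrong, Y, X)
            assert h_wrong >= h_true - 3 * sem

    def test_duplication_invariance_and_empty_rejection(self):
        rng = np.random.default_rng(5)
        Y, X = self._gaussian_pairs(0.5, 500, rng)
        model = MCGSMParams(
            K=np.ones((1, 1, 1)), alphas=np.ones((1, 1)),
            A=np.full((1, 1, 1), 0.5), Sigma=np.full((1, 1, 1), 0.75),
        )
        e1, _ = conditional_cross_entropy(model, Y, X)
        e2, _ = conditional_cross_entropy(model, np.tile(Y, (2, 1)), np.tile(X, (2, 1)))
        assert e1 == pytest.approx(e2, abs=1e-12)
        with pytest.raises(ValueError):
            conditional_cross_entropy(model, np.empty((0, 1)), np.empty((0, 1)))


class TestRateReport:
    def test_identity_enforced(self):
        rep = cross_mir(4.0, 3.1)
        assert rep.cross_mir == pytest.approx(0.9)
        # negative cross-MIR is allowed (bad model below the marginal)
        assert cross_mir(1.0, 2.0).cross_mir == pytest.approx(-1.0)


class TestPhaseScramble:
    def test_amplitude_spectrum_preserved(self):
        img = np.random.default_rng(6).standard_normal((32, 48))
        out = phase_scramble(img, seed=0)
        assert np.allclose(
            np.abs(np.fft.fft2(out)), np.abs(np.fft.fft2(img)), atol=1e-10
        )

    def test_constant_image_unchanged(self):
        img = np.full((16, 16), 2.5)
        assert np.allclose(phase_scramble(img, seed=1), img, atol=1e-12)

    def test_autocorrelation_preserved(self):
        # Wiener-Khinchin: autocorrelation = IFFT of the power spectrum
        img = np.random.default_rng(7).standard_normal((32, 32))
        img += np.roll(img, 1, axis=1)  # correlated field
        out = phase_scramble(img, seed=2)
        ac_in = np.real(np.fft.ifft2(np.abs(np.fft.fft2(img)) ** 2))
        ac_out = np.real(np.fft.ifft2(np.abs(np.fft.fft2(out)) ** 2))
        assert np.allclose(ac_in, ac_out, atol=1e-8)

    def test_mean_retained(self):
        img = np.random.default_rng(8).standard_normal((16, 16)) + 5.0
        assert phase_scramble(img, seed=3).mean() == pytest.approx(img.mean(), abs=1e-10)


class TestLpFit:
    def test_scale_equivariance(self):
        pairs = lp_pairs(1.0, 2.0, 1.0, 20_000, seed=0)
        f1 = fit_lp(pairs)
        f2 = fit_lp(10.0 * pairs)
        assert f2.p == pytest.approx(f1.p, abs=1e-3)
        assert f2.radial_scale == pytest.approx(10 * f1.radial_scale, rel=1e-2)

    def test_swap_symmetry(self):
        pairs = lp_pairs(0.8, 2.0, 1.0, 20_000, seed=1)
        swapped = pairs[:, ::-1]
        assert fit_lp(np.vstack([pairs, swapped])).p == pytest.approx(
            fit_lp(np.vstack([swapped, pairs])).p, abs=1e-9
        )

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            fit_lp(np.zeros((50, 2)))

    def test_gamma_mle_matches_scipy(self):
        from scipy.stats import gamma as sp_gamma

        from mcgsm.evaluation import _gamma_mle

        r = np.random.default_rng(11).gamma(2.3, 0.8, size=5000)
        shape, scale, _ = _gamma_mle(r)
        sp_shape, _, sp_scale = sp_gamma.fit(r, floc=0)
        assert shape == pytest.approx(sp_shape, rel=1e-4)
        assert scale == pytest.approx(sp_scale, rel=1e-4)


class TestFilterPairs:
    def test_kernel_zero_sum_unit_norm(self):
        k = _dog_kernel(1.5)
        assert k.sum() == pytest.approx(0.0, abs=1e-12)
        assert np.sum(k * k) == pytest.approx(1.0, abs=1e-12)

    def test_gaussian_images_are_l2_spherical(self):
        rng = np.random.default_rng(9)
        imgs = [rng.standard_normal((96, 96)) for _ in range(6)]
        fits = filter_pair_statistic(imgs, offsets=[1, 4], seed=0)
        for _, f in fits:
            assert f.p == pytest.approx(2.0, abs=0.1)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            filter_pair_statistic([np.zeros((20, 20))], offsets=[1], min_pairs=10**6)


class TestScaleInvariance:
    def test_white_noise_profile(self):
        # white noise is exactly self-similar under the Haar DC chain:
        # per-scale cross-MIR stays near zero and the variance-corrected
        # AC conditional entropies agree across scales
        rng = np.random.default_rng(10)
        train = [rng.standard_normal((64, 64)) for _ in range(6)]
        test = [rng.standard_normal((64, 64)) for _ in range(4)]
        prof = scale_invariance_profile(
            train, test, L=1, C=1, S=1, k=3, n_samples=8000, seed=0
        )
        for _, mir, sem in prof["per_scale_mir"]:
            assert abs(mir) < max(3 * sem, 0.05)
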