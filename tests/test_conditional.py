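"""MCGSM conditional density: gates, experts, gradients, training."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import kstest, norm

from mcgsm import (
    GSMParams,
    MCGSMParams,
    MoGSMParams,
    ParamStructure,
    TrainOptions,
    conditional_logpdf,
    conditional_sample,
    from_joint,
    gate_log_posteriors,
    mogsm_logpdf,
    negloglik_and_gradient,
    train,
)

from conftest import random_mcgsm, random_spd


def random_joint(m, d, C, S, rng):
    comps = tuple(
        GSMParams(covariance=random_spd(m + d, rng), scales=np.exp(rng.standard_normal(S)))
        for _ in range(C)
    )
    return MoGSMParams(components=comps)


class TestGates:
    def test_identical_components_are_uniform(self):
        rng = np.random.default_rng(0)
        K = random_spd(3, rng)
        params = MCGSMParams(
            K=np.stack([K, K]),
            alphas=np.ones((2, 2)),
            A=np.zeros((2, 1, 3)),
            Sigma=np.ones((2, 1, 1)),
        )
        w = np.exp(gate_log_posteriors(rng.standard_normal(3), params))
        assert np.allclose(w, 0.25, atol=1e-12)

    def test_single_expert_weight_is_one(self):
        params = MCGSMParams(
            K=np.eye(2)[None], alphas=np.ones((1, 1)), A=np.zeros((1, 1, 2)),
            Sigma=np.ones((1, 1, 1)),
        )
        assert gate_log_posteriors(np.ones(2), params) == pytest.approx(0.0, abs=1e-12)

    def test_matches_bayes_posterior_of_joint(self):
        # gate weights are P(c, s | y) under the joint MoGSM marginal on y
        rng = np.random.default_rng(1)
        joint = random_joint(3, 1, C=2, S=2, rng=rng)
        params = from_joint(joint, split=3)
        y = rng.standard_normal(3)
        log_post = np.empty((2, 2))
        for c, comp in enumerate(joint.components):
            for s, a in enumerate(comp.scales):
                cov = comp.covariance[:3, :3] / a
                inv = np.linalg.inv(cov)
                log_post[c, s] = -0.5 * (
                    y @ inv @ y + np.log(np.linalg.det(cov)) + 3 * np.log(2 * np.pi)
                )
        log_post -= np.log(np.exp(log_post).sum())
        # from_joint re-gauges the scales but the gate posterior is gauge-invariant
        assert np.allclose(gate_log_posteriors(y, params), log_post, atol=1e-10)


class TestConditionalDensity:
    def test_linear_gaussian_reduction(self):
        params = MCGSMParams(
            K=np.ones((1, 1, 1)), alphas=np.ones((1, 1)),
            A=np.full((1, 1, 1), 0.5), Sigma=np.ones((1, 1, 1)),
        )
        # residual zero: log N(0; 0, 1)
        got = conditional_logpdf(np.array([0.5]), np.array([1.0]), params)
        assert got == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)

    def test_quadrature_normalization(self):
        rng = np.random.default_rng(2)
        params = random_mcgsm(m=2, d=1, C=2, S=2, rng=rng)
        y = rng.standard_normal(2)
        total, _ = quad(
            lambda x: np.exp(conditional_logpdf(np.array([x]), y, params)),
            -50, 50, limit=300,
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_bayes_identity_for_random_joints(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            m, d = int(rng.integers(1, 4)), int(rng.integers(1, 3))
            joint = random_joint(m, d, C=2, S=2, rng=rng)
            cond = from_joint(joint, split=m)
            marg = MoGSMParams(
                components=tuple(
                    GSMParams(covariance=c.covariance[:m, :m], scales=c.scales)
                    for c in joint.components
                )
            )
            y = rng.standard_normal(m)
            x = rng.standard_normal(d)
            lhs = conditional_logpdf(x, y, cond)
            rhs = mogsm_logpdf(np.concatenate([y, x]), joint) - mogsm_logpdf(y, marg)
            assert lhs == pytest.approx(rhs, abs=1e-10)

    def test_gauge_invariance(self):
        rng = np.random.default_rng(4)
        params = random_mcgsm(m=3, d=2, C=2, S=2, rng=rng)
        t = 2.7
        rescaled = MCGSMParams(
            K=params.K * t, alphas=params.alphas / t, A=params.A, Sigma=params.Sigma / t
        )
        y = rng.standard_normal(3)
        x = rng.standard_normal(2)
        assert conditional_logpdf(x, y, rescaled) == pytest.approx(
            conditional_logpdf(x, y, params), abs=1e-12
        )
        canon = rescaled.canonicalized()
        assert np.allclose(np.sum(np.log(canon.alphas), axis=1), 0.0, atol=1e-12)
        assert conditional_logpdf(x, y, canon) == pytest.approx(
            conditional_logpdf(x, y, params), abs=1e-12
        )

    def test_special_case_tower(self):
        """C=S=1 is a conditional Gaussian; C=1,S>1 a conditional GSM."""
        rng = np.random.default_rng(5)
        y = rng.standard_normal(2)
        x = rng.standard_normal(1)
        # CG: ignore gates entirely
        A = rng.standard_normal((1, 1, 2))
        cg = MCGSMParams(K=random_spd(2, rng)[None], alphas=np.ones((1, 1)), A=A,
                         Sigma=np.array([[[0.7]]]))
        expected = norm.logpdf(x[0], loc=float((A[0] @ y)[0]), scale=np.sqrt(0.7))
        assert conditional_logpdf(x, y, cg) == pytest.approx(expected, abs=1e-12)
        # CGSM: gates over scales only, explicit two-term computation
        K = random_spd(2, rng)
        alphas = np.array([[0.5, 2.0]])
        cgsm = MCGSMParams(K=K[None], alphas=alphas, A=A, Sigma=np.array([[[0.7]]]))
        quad_y = y @ K @ y
        logw = 1.0 * np.log(alphas[0]) - 0.5 * alphas[0] * quad_y  # (m/2) log a - a/2 yKy
        logw -= np.log(np.exp(logw).sum())
        dens = sum(
            np.exp(lw) * norm.pdf(x[0], loc=float((A[0] @ y)[0]), scale=np.sqrt(0.7 / a))
            for lw, a in zip(logw, alphas[0])
        )
        assert conditional_logpdf(x, y, cgsm) == pytest.approx(np.log(dens), abs=1e-10)


class TestFromJoint:
    def test_schur_complement_example(self):
        joint = MoGSMParams(
            components=(GSMParams(covariance=[[1.0, 0.5], [0.5, 1.0]], scales=[1.0]),)
        )
        p = from_joint(joint, split=1)
        assert p.K[0, 0, 0] == pytest.approx(1.0)
        assert p.A[0, 0, 0] == pytest.approx(0.5)
        assert p.Sigma[0, 0, 0] == pytest.approx(0.75)

    def test_identity_joint_gives_independence(self):
        joint = MoGSMParams(components=(GSMParams(covariance=np.eye(4), scales=[1.0]),))
        p = from_joint(joint, split=2)
        assert np.allclose(p.A, 0.0)
        assert np.allclose(p.Sigma[0], np.eye(2))

    def test_invalid_split_rejected(self):
        joint = MoGSMParams(components=(GSMParams(covariance=np.eye(3), scales=[1.0]),))
        with pytest.raises(ValueError):
            from_joint(joint, split=3)
        with pytest.raises(ValueError):
            from_joint(joint, split=0)


class TestFlatParametrization:
    def test_encode_decode_roundtrip(self):
        rng = np.random.default_rng(6)
        params = random_mcgsm(m=3, d=2, C=2, S=3, rng=rng)
        struct = ParamStructure(m=3, d=2, C=2, S=3)
        back = struct.decode(struct.encode(params))
        assert np.allclose(back.K, params.K, atol=1e-12)
        assert np.allclose(back.alphas, params.alphas, atol=1e-12)
        assert np.allclose(back.A, params.A, atol=1e-12)
        assert np.allclose(back.Sigma, params.Sigma, atol=1e-12)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(7)
        struct = ParamStructure(m=4, d=1, C=2, S=2)
        for _ in range(3):
            theta = 0.3 * rng.standard_normal(struct.size)
            Y = rng.standard_normal((50, 4))
            X = rng.standard_normal((50, 1))
            _, g = negloglik_and_gradient(theta, struct, Y, X)
            eps = 1e-6
            for i in rng.choice(struct.size, size=10, replace=False):
                tp, tm = theta.copy(), theta.copy()
                tp[i] += eps
                tm[i] -= eps
                num = (
                    negloglik_and_gradient(tp, struct, Y, X)[0]
                    - negloglik_and_gradient(tm, struct, Y, X)[0]
                ) / (2 * eps)
                assert g[i] == pytest.approx(num, rel=1e-5, abs=1e-10)

    def test_linear_regression_gradient_limit(self):
        # at C=S=1 the gradient w.r.t. A is the least-squares gradient
        rng = np.random.default_rng(8)
        struct = ParamStructure(m=3, d=1, C=1, S=1)
        A = rng.standard_normal((1, 1, 3))
        params = MCGSMParams(K=np.eye(3)[None], alphas=np.ones((1, 1)), A=A,
                             Sigma=np.ones((1, 1, 1)))
        theta = struct.encode(params)
        Y = rng.standard_normal((100, 3))
        X = rng.standard_normal((100, 1))
        _, g = negloglik_and_gradient(theta, struct, Y, X)
        # locate the A block in the flat layout
        o = struct.n_tril_K + 1
        gA = g[o:o + 3]
        resid = X - Y @ A[0].T
        expected = -(resid * Y).mean(axis=0)  # d/dA of 0.5*mean(resid^2)
        assert np.allclose(gA, expected, atol=1e-10)

    def test_duplicated_rows_leave_mean_objective_unchanged(self):
        rng = np.random.default_rng(9)
        struct = ParamStructure(m=2, d=1, C=2, S=2)
        theta = 0.2 * rng.standard_normal(struct.size)
        Y = rng.standard_normal((30, 2))
        X = rng.standard_normal((30, 1))
        f1, _ = negloglik_and_gradient(theta, struct, Y, X)
        f2, _ = negloglik_and_gradient(theta, struct, np.tile(Y, (2, 1)), np.tile(X, (2, 1)))
        assert f1 == pytest.approx(f2, abs=1e-12)


class TestSampling:
    def test_moments_and_determinism(self):
        params = MCGSMParams(
            K=np.eye(2)[None], alphas=np.ones((1, 1)), A=np.zeros((1, 1, 2)),
            Sigma=np.ones((1, 1, 1)),
        )
        Y = np.zeros((100_000, 2))
        x1 = conditional_sample(Y, params, seed=0)
        x2 = conditional_sample(Y, params, seed=0)
        assert np.array_equal(x1, x2)
        assert abs(x1.mean()) < 0.01
        assert x1.var() == pytest.approx(1.0, abs=0.02)

    def test_sampler_matches_density(self):
        rng = np.random.default_rng(10)
        params = random_mcgsm(m=2, d=1, C=2, S=2, rng=rng)
        y = rng.standard_normal(2)
        draws = conditional_sample(np.tile(y, (100_000, 1)), params, seed=1).ravel()
        grid = np.linspace(draws.min() - 1, draws.max() + 1, 4001)
        pdf = np.exp(conditional_logpdf(grid[:, None], np.tile(y, (4001, 1)), params))
        cdf_grid = np.cumsum(pdf) * (grid[1] - grid[0])
        cdf_grid /= cdf_grid[-1]
        stat = kstest(draws, lambda v: np.interp(v, grid, cdf_grid)).statistic
        assert stat < 0.01


class TestTraining:
    def test_recovers_linear_gaussian(self):
        rng = np.random.default_rng(11)
        A_true = np.array([[0.5, -0.3, 0.2]])
        Y = rng.standard_normal((20_000, 3))
        X = Y @ A_true.T + 0.5 * rng.standard_normal((20_000, 1))
        params, info = train(Y, X, C=1, S=1, seed=0)
        assert np.abs(params.A[0] - A_true).max() < 0.02
        assert params.Sigma[0, 0, 0] == pytest.approx(0.25, rel=0.05)
        assert info["final_objective"] <= info["initial_objective"] + 1e-12

    def test_descent_from_em_initialization(self):
        rng = np.random.default_rng(12)
        Y = rng.standard_normal((2000, 2))
        X = np.tanh(Y[:, :1]) + 0.3 * rng.standard_normal((2000, 1))
        _, info = train(Y, X, C=2, S=2, seed=0,
                        opts=TrainOptions(max_iter=60, em_max_iter=15))
        assert info["final_objective"] <= info["initial_objective"] + 1e-12
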