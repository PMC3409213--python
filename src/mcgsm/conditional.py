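"""Mixtures of conditional Gaussian scale mixtures (MCGSM).

The conditional density of a pixel (or coefficient vector) x given its
neighborhood y is a mixture-of-experts model

    p(x | y) = sum_{c,s} w_{cs}(y) N(x; A_c y, Sigma_c / alpha_{cs})

whose gates weight (component, scale) pairs by Gaussian energies of the
input,

    log w_{cs}(y) = (m/2) log alpha_{cs} + (1/2) log|K_c|
                    - (alpha_{cs}/2) y^T K_c y  + const(y),

and whose experts are linear-Gaussian predictors.  This is exactly the
conditional distribution obtained by conditioning an equal-weight zero-mean
mixture of GSMs over the joint vector (y, x); :func:`from_joint` performs
that reduction in closed form via Schur complements.

Training maximizes the conditional log-likelihood with BFGS on an
unconstrained parametrization (Cholesky factors with log-diagonals for K_c
and Sigma_c, log-scales in a per-component zero-sum gauge), initialized from
an EM-fitted joint mixture of GSMs.

The model family nests the standard baselines: C=S=1 is the conditional
Gaussian (CG), C>1, S=1 a zero-mean mixture of conditional Gaussians (MCG),
and C=1, S>1 a conditional Gaussian scale mixture (CGSM).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize
from scipy.special import logsumexp

from .gsm import MoGSMParams, _validate_covariance, mogsm_fit_em

import logging

_logger = logging.getLogger(__name__)

__all__ = [
    "MCGSMParams",
    "ParamStructure",
    "gate_log_posteriors",
    "conditional_logpdf",
    "conditional_sample",
    "negloglik_and_gradient",
    "from_joint",
    "train",
    "TrainOptions",
]

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class MCGSMParams:
    """Parameters of a mixture of conditional Gaussian scale mixtures.

    Attributes
    ----------
    K : (C, m, m) gate precision matrices (positive definite).
    alphas : (C, S) positive scale multipliers.
    A : (C, d, m) linear predictor matrices.
    Sigma : (C, d, d) expert covariances (positive definite); the expert at
        (c, s) has covariance ``Sigma_c / alpha_{cs}``.
    """

    K: np.ndarray
    alphas: np.ndarray
    A: np.ndarray
    Sigma: np.ndarray

    def __post_init__(self):
        K = np.asarray(self.K, dtype=float)
        alphas = np.asarray(self.alphas, dtype=float)
        A = np.asarray(self.A, dtype=float)
        Sigma = np.asarray(self.Sigma, dtype=float)
        if K.ndim != 3 or K.shape[1] != K.shape[2]:
            raise ValueError("K must have shape (C, m, m)")
        C, m, _ = K.shape
        if alphas.shape[0] != C or alphas.ndim != 2:
            raise ValueError("alphas must have shape (C, S)")
        if A.shape[0] != C or A.ndim != 3 or A.shape[2] != m:
            raise ValueError("A must have shape (C, d, m)")
        d = A.shape[1]
        if Sigma.shape != (C, d, d):
            raise ValueError("Sigma must have shape (C, d, d)")
        if np.any(alphas <= 0):
            raise ValueError("all scales must be positive")
        for c in range(C):
            _validate_covariance(K[c], f"K[{c}]")
            _validate_covariance(Sigma[c], f"Sigma[{c}]")
        object.__setattr__(self, "K", K)
        object.__setattr__(self, "alphas", alphas)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "Sigma", Sigma)

    @property
    def in_dim(self) -> int:
        return self.K.shape[1]

    @property
    def out_dim(self) -> int:
        return self.A.shape[1]

    @property
    def n_components(self) -> int:
        return self.K.shape[0]

    @property
    def n_scales(self) -> int:
        return self.alphas.shape[1]

    def canonicalized(self) -> "MCGSMParams":
        """Return an equivalent model in the zero-sum log-scale gauge.

        The transformation (K -> tK, alpha -> alpha/t, Sigma -> Sigma/t)
        leaves the conditional density invariant; pick t so that
        sum_s log alpha_{cs} = 0 per component.
        """
        t = np.exp(np.mean(np.log(self.alphas), axis=1))  # (C,)
        return MCGSMParams(
            K=self.K * t[:, None, None],
            alphas=self.alphas / t[:, None],
            A=self.A.copy(),
            Sigma=self.Sigma / t[:, None, None],
        )


def _as_batch(v: np.ndarray, dim: int, name: str) -> tuple[np.ndarray, bool]:
    v = np.asarray(v, dtype=float)
    single = v.ndim == 1
    V = np.atleast_2d(v)
    if V.shape[1] != dim:
        raise ValueError(f"{name} must have {dim} columns, got {V.shape[1]}")
    return V, single


def _gate_energies(Y: np.ndarray, params: MCGSMParams) -> np.ndarray:
    """Unnormalized gate log-weights, shape (n, C, S)."""
    C, m, _ = params.K.shape
    quad = np.einsum("ni,cij,nj->nc", Y, params.K, Y)
    logdet = np.array([2.0 * np.sum(np.log(np.diag(cholesky(params.K[c], lower=True))))
                       for c in range(C)])
    return (
        0.5 * m * np.log(params.alphas)[None, :, :]
        + 0.5 * logdet[None, :, None]
        - 0.5 * quad[:, :, None] * params.alphas[None, :, :]
    )


def gate_log_posteriors(y: np.ndarray, params: MCGSMParams) -> np.ndarray:
    """Normalized log gate weights log P(c, s | y); (C, S) or (n, C, S)."""
    Y, single = _as_batch(y, params.in_dim, "y")
    g = _gate_energies(Y, params)
    g -= logsumexp(g.reshape(len(Y), -1), axis=1)[:, None, None]
    return g[0] if single else g


def _expert_logpdfs(X: np.ndarray, Y: np.ndarray, params: MCGSMParams) -> np.ndarray:
    """log N(x; A_c y, Sigma_c / alpha_{cs}) for all (c, s); (n, C, S)."""
    C, d, _ = params.Sigma.shape
    n = len(X)
    out = np.empty((n, C, params.n_scales))
    for c in range(C):
        L = cholesky(params.Sigma[c], lower=True)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        R = X - Y @ params.A[c].T
        z = solve_triangular(L, R.T, lower=True)
        quad = np.einsum("ij,ij->j", z, z)
        out[:, c, :] = (
            -0.5 * d * _LOG_2PI
            - 0.5 * logdet
            + 0.5 * d * np.log(params.alphas[c])[None, :]
            - 0.5 * quad[:, None] * params.alphas[c][None, :]
        )
    return out


def conditional_logpdf(x: np.ndarray, y: np.ndarray, params: MCGSMParams) -> float | np.ndarray:
    """log p(x | y) under the MCGSM; batched when x, y are matrices."""
    Y, single_y = _as_batch(y, params.in_dim, "y")
    X, single_x = _as_batch(x, params.out_dim, "x")
    if len(X) != len(Y):
        raise ValueError("x and y must have the same number of rows")
    g = _gate_energies(Y, params)
    e = _expert_logpdfs(X, Y, params)
    n = len(X)
    ll = (
        logsumexp((g + e).reshape(n, -1), axis=1)
        - logsumexp(g.reshape(n, -1), axis=1)
    )
    return float(ll[0]) if (single_x and single_y) else ll


def conditional_sample(y: np.ndarray, params: MCGSMParams, seed) -> np.ndarray:
    """Draw x ~ p(x | y): pick (c, s) from the gates, then the expert Gaussian."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Y, single = _as_batch(y, params.in_dim, "y")
    n = len(Y)
    d = params.out_dim
    S = params.n_scales
    logw = gate_log_posteriors(Y, params)
    if single:
        logw = logw[None]
    w = np.exp(logw.reshape(n, -1))
    w /= w.sum(axis=1, keepdims=True)
    u = rng.random(n)
    idx = (np.cumsum(w, axis=1) < u[:, None]).sum(axis=1)
    c, s = np.divmod(idx, S)
    chols = np.stack([cholesky(params.Sigma[k], lower=True) for k in range(params.n_components)])
    eps = rng.standard_normal((n, d))
    mean = np.einsum("nij,nj->ni", params.A[c], Y)
    x = mean + np.einsum("nij,nj->ni", chols[c], eps) / np.sqrt(params.alphas[c, s])[:, None]
    return x[0] if single else x


# ---------------------------------------------------------------------------
# Unconstrained flat parametrization


def _tril_indices(k: int):
    return np.tril_indices(k)


@dataclass(frozen=True)
class ParamStructure:
    """Index map between MCGSMParams and an unconstrained flat vector.

    Layout: [chol(K) per component | log alpha (C*S) | A (C*d*m) |
    chol(Sigma) per component].  Cholesky factors are stored row-major over
    their lower triangles with the diagonal entries replaced by their logs,
    so any real vector decodes to valid positive-definite matrices.  Log
    scales are projected to zero mean per component on decode, which removes
    the gauge flat direction from the optimization.
    """

    m: int
    d: int
    C: int
    S: int

    @property
    def n_tril_K(self) -> int:
        return self.m * (self.m + 1) // 2

    @property
    def n_tril_S(self) -> int:
        return self.d * (self.d + 1) // 2

    @property
    def size(self) -> int:
        return self.C * (self.n_tril_K + self.S + self.d * self.m + self.n_tril_S)

    def _chol_to_vec(self, L: np.ndarray) -> np.ndarray:
        L = L.copy()
        di = np.diag_indices(L.shape[0])
        L[di] = np.log(L[di])
        return L[np.tril_indices(L.shape[0])]

    def _vec_to_chol(self, v: np.ndarray, k: int) -> np.ndarray:
        L = np.zeros((k, k))
        L[np.tril_indices(k)] = v
        di = np.diag_indices(k)
        L[di] = np.exp(L[di])
        return L

    def encode(self, params: MCGSMParams) -> np.ndarray:
        if (params.in_dim, params.out_dim, params.n_components, params.n_scales) != (
            self.m, self.d, self.C, self.S,
        ):
            raise ValueError("parameter shapes do not match structure")
        parts = []
        for c in range(self.C):
            parts.append(self._chol_to_vec(cholesky(params.K[c], lower=True)))
        la = np.log(params.alphas)
        parts.append((la - la.mean(axis=1, keepdims=True)).ravel())
        parts.append(params.A.ravel())
        for c in range(self.C):
            parts.append(self._chol_to_vec(cholesky(params.Sigma[c], lower=True)))
        return np.concatenate(parts)

    def decode_arrays(self, theta: np.ndarray):
        """Return (LK, alphas, A, LS): Cholesky factors and decoded arrays."""
        theta = np.asarray(theta, dtype=float)
        if theta.size != self.size:
            raise ValueError(f"expected vector of length {self.size}, got {theta.size}")
        o = 0
        LK = np.empty((self.C, self.m, self.m))
        for c in range(self.C):
            LK[c] = self._vec_to_chol(theta[o:o + self.n_tril_K], self.m)
            o += self.n_tril_K
        u = theta[o:o + self.C * self.S].reshape(self.C, self.S)
        o += self.C * self.S
        alphas = np.exp(u - u.mean(axis=1, keepdims=True))
        A = theta[o:o + self.C * self.d * self.m].reshape(self.C, self.d, self.m)
        o += self.C * self.d * self.m
        LS = np.empty((self.C, self.d, self.d))
        for c in range(self.C):
            LS[c] = self._vec_to_chol(theta[o:o + self.n_tril_S], self.d)
            o += self.n_tril_S
        return LK, alphas, A, LS

    def decode(self, theta: np.ndarray) -> MCGSMParams:
        LK, alphas, A, LS = self.decode_arrays(theta)
        K = np.einsum("cij,ckj->cik", LK, LK)
        Sigma = np.einsum("cij,ckj->cik", LS, LS)
        # near-degenerate factors (underflowed log-diagonals) can make the
        # product numerically indefinite; floor with escalating diagonal
        # jitter starting at 1e-9 of the mean diagonal
        for M in (K, Sigma):
            for c in range(self.C):
                jitter = 1e-9 * max(np.mean(np.diag(M[c])), np.finfo(float).tiny)
                while True:
                    try:
                        cholesky(M[c], lower=True)
                        break
                    except np.linalg.LinAlgError:
                        _logger.warning(
                            "adding diagonal jitter %.1e to keep component %d positive definite",
                            jitter, c,
                        )
                        M[c] += jitter * np.eye(M[c].shape[0])
                        jitter *= 10.0
        return MCGSMParams(K=K, alphas=alphas, A=A, Sigma=Sigma)


def _chol_grad(dM: np.ndarray, L: np.ndarray) -> np.ndarray:
    """Gradient w.r.t. the log-diag Cholesky vector given symmetric dM = df/dM, M = L L^T."""
    G = 2.0 * np.tril(dM @ L)
    di = np.diag_indices(L.shape[0])
    G[di] *= L[di]
    return G[np.tril_indices(L.shape[0])]


def negloglik_and_gradient(
    theta: np.ndarray,
    struct: ParamStructure,
    Y: np.ndarray,
    X: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Mean negative conditional log-likelihood and its exact gradient.

    The objective decomposes per data point as

        -log p(x|y) = -[ LSE_{cs}(g + e) - LSE_{cs}(g) ]

    with gate energies g and expert log-densities e, so the gradient is a
    difference of posterior-weighted sufficient statistics: gate parameters
    receive weights (q - w), expert parameters weights q, where q and w are
    the softmax of (g + e) and g respectively.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = len(Y)
    if n < 1 or len(X) != n:
        raise ValueError("Y and X must be non-empty with matching rows")
    m, d, C, S = struct.m, struct.d, struct.C, struct.S
    LK, alphas, A, LS = struct.decode_arrays(theta)
    la = np.log(alphas)

    # energies
    g = np.empty((n, C, S))
    e = np.empty((n, C, S))
    quadK = np.empty((n, C))
    quadS = np.empty((n, C))
    logdetK = np.empty(C)
    logdetS = np.empty(C)
    R = np.empty((C, n, d))
    for c in range(C):
        T = Y @ LK[c]  # y^T K y = ||L^T y||^2
        quadK[:, c] = np.einsum("ni,ni->n", T, T)
        logdetK[c] = 2.0 * np.sum(np.log(np.diag(LK[c])))
        R[c] = X - Y @ A[c].T
        z = solve_triangular(LS[c], R[c].T, lower=True)
        quadS[:, c] = np.einsum("in,in->n", z, z)
        logdetS[c] = 2.0 * np.sum(np.log(np.diag(LS[c])))
    g[:] = (0.5 * m * la)[None] + 0.5 * logdetK[None, :, None] \
        - 0.5 * quadK[:, :, None] * alphas[None]
    e[:] = -0.5 * d * _LOG_2PI + (0.5 * d * la)[None] - 0.5 * logdetS[None, :, None] \
        - 0.5 * quadS[:, :, None] * alphas[None]

    ge = (g + e).reshape(n, -1)
    gg = g.reshape(n, -1)
    lse_ge = logsumexp(ge, axis=1)
    lse_g = logsumexp(gg, axis=1)
    f = -float(np.mean(lse_ge - lse_g))
    if not np.isfinite(f):
        raise FloatingPointError("non-finite objective; parameters out of range")

    q = np.exp(ge - lse_ge[:, None]).reshape(n, C, S)
    w = np.exp(gg - lse_g[:, None]).reshape(n, C, S)
    D = q - w  # gate weights

    gK = np.empty((C, struct.n_tril_K))
    gA = np.empty((C, d, m))
    gS = np.empty((C, struct.n_tril_S))
    gLa = np.empty((C, S))
    for c in range(C):
        Dc = D[:, c, :]  # (n, S)
        qc = q[:, c, :]
        a_c = Dc.sum()
        b = Dc @ alphas[c]  # (n,)
        # dK_c = 1/2 a_c K^{-1} - 1/2 Y^T diag(b) Y
        Kinv = cho_solve((LK[c], True), np.eye(m))
        dK = 0.5 * a_c * Kinv - 0.5 * (Y.T * b) @ Y
        gK[c] = _chol_grad(dK, LK[c])
        # log alpha
        gLa[c] = (
            Dc * (0.5 * m - 0.5 * quadK[:, c][:, None] * alphas[c][None])
            + qc * (0.5 * d - 0.5 * quadS[:, c][:, None] * alphas[c][None])
        ).sum(axis=0)
        # A_c and Sigma_c use expert weights sum_s q alpha
        cvec = qc @ alphas[c]  # (n,)
        P = cho_solve((LS[c], True), np.eye(d))
        gA[c] = P @ (R[c].T * cvec) @ Y
        Mc = (R[c].T * cvec) @ R[c]
        dS = -0.5 * qc.sum() * P + 0.5 * P @ Mc @ P
        gS[c] = _chol_grad(dS, LS[c])
    # zero-mean projection of the log-scale gradient (decode subtracts the mean)
    gLa -= gLa.mean(axis=1, keepdims=True)

    grad = -np.concatenate(
        [gK.ravel(), gLa.ravel(), gA.ravel(), gS.ravel()]
    ) / n
    return f, grad


def from_joint(joint: MoGSMParams, split: int) -> MCGSMParams:
    """Conditionalize a joint MoGSM over (y, x) into an MCGSM, y = first `split` dims.

    Per component with joint covariance blocks [[S_yy, S_yx], [S_xy, S_xx]]:
    K_c = S_yy^{-1}, A_c = S_xy S_yy^{-1}, Sigma_c = S_xx - S_xy S_yy^{-1} S_yx.
    The scales carry over unchanged and are then re-gauged.
    """
    m = int(split)
    dim = joint.dim
    d = dim - m
    if not (1 <= m < dim):
        raise ValueError(f"split must be in [1, dim-1], got {m} for dim {dim}")
    C = joint.n_components
    K = np.empty((C, m, m))
    A = np.empty((C, d, m))
    Sigma = np.empty((C, d, d))
    for c, comp in enumerate(joint.components):
        cov = comp.covariance
        Syy = cov[:m, :m]
        Syx = cov[:m, m:]
        Sxx = cov[m:, m:]
        try:
            cf = cho_factor(Syy, lower=True)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular input block in component {c}") from exc
        K[c] = cho_solve(cf, np.eye(m))
        K[c] = 0.5 * (K[c] + K[c].T)
        A[c] = cho_solve(cf, Syx).T
        Sigma[c] = Sxx - Syx.T @ cho_solve(cf, Syx)
        Sigma[c] = 0.5 * (Sigma[c] + Sigma[c].T)
    params = MCGSMParams(K=K, alphas=joint.scales().copy(), A=A, Sigma=Sigma)
    return params.canonicalized()


@dataclass
class TrainOptions:
    """Knobs for MCGSM maximum-likelihood training."""

    max_iter: int = 500
    gtol: float = 1e-6
    em_max_iter: int = 50
    em_tol: float = 1e-6
    jitter: float = 1e-9
    restarts: int = 2
    # multi-start: train n_init candidates from different EM seeds and keep
    # the one with the best held-out likelihood on val_fraction of the data.
    # Mixture likelihoods are unbounded (a component can shrink onto a few
    # training points), so selection must be on held-out data.
    n_init: int = 1
    val_fraction: float = 0.1


def train(
    Y: np.ndarray,
    X: np.ndarray,
    C: int,
    S: int,
    seed=0,
    opts: TrainOptions | None = None,
) -> tuple[MCGSMParams, dict]:
    """Maximum-likelihood MCGSM training.

    Fits an equal-weight MoGSM to the concatenated (y, x) vectors by EM,
    conditionalizes it via :func:`from_joint` as initialization, then runs
    BFGS on the exact conditional negative log-likelihood gradient.

    Returns the canonical-gauge parameters and a trace dict with the EM
    log-likelihood trace, the BFGS objective trace, and the scipy result.
    """
    opts = opts or TrainOptions()
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]

    if opts.n_init > 1:
        rng = np.random.default_rng(seed)
        n = len(Y)
        perm = rng.permutation(n)
        n_val = max(1, int(round(opts.val_fraction * n)))
        val, fit_idx = perm[:n_val], perm[n_val:]
        sub_opts = dataclasses.replace(opts, n_init=1)
        best = None
        for i in range(opts.n_init):
            params_i, info_i = train(
                Y[fit_idx], X[fit_idx], C, S,
                seed=int(rng.integers(2**31)), opts=sub_opts,
            )
            val_nll = -float(np.mean(conditional_logpdf(X[val], Y[val], params_i)))
            info_i["validation_negloglik"] = val_nll
            if best is None or val_nll < best[2]:
                best = (params_i, info_i, val_nll)
        params, info = best[0], best[1]
        info["n_init"] = opts.n_init
        return params, info

    m = Y.shape[1]
    d = X.shape[1]
    Z = np.concatenate([Y, X], axis=1)

    joint, em_trace = mogsm_fit_em(
        Z, C=C, S=S, seed=seed, max_iter=opts.em_max_iter, tol=opts.em_tol
    )
    try:
        init = from_joint(joint, split=m)
    except ValueError:
        # singular input block: jittered restart
        covs = joint.covariances() + opts.jitter * np.eye(m + d)
        joint = MoGSMParams(
            components=tuple(
                replace(comp, covariance=covs[c]) for c, comp in enumerate(joint.components)
            )
        )
        init = from_joint(joint, split=m)

    struct = ParamStructure(m=m, d=d, C=C, S=S)
    theta0 = struct.encode(init)
    trace: list[float] = []

    def objective(theta):
        f, grad = negloglik_and_gradient(theta, struct, Y, X)
        trace.append(f)
        return f, grad

    res = minimize(
        objective,
        theta0,
        jac=True,
        method="BFGS",
        options={"gtol": opts.gtol, "maxiter": opts.max_iter},
    )
    # BFGS can abort with "precision loss" far from a stationary point on
    # heavy-tailed objectives; restarting with a fresh Hessian recovers.
    for _ in range(opts.restarts):
        if res.status != 2 or np.linalg.norm(res.jac) <= 10 * opts.gtol:
            break
        prev_fun = res.fun
        res2 = minimize(
            objective,
            res.x,
            jac=True,
            method="BFGS",
            options={"gtol": opts.gtol, "maxiter": opts.max_iter},
        )
        if res2.fun >= prev_fun:
            break
        res = res2
    f0 = negloglik_and_gradient(theta0, struct, Y, X)[0]
    theta = res.x if res.fun <= f0 else theta0  # descent contract
    params = struct.decode(theta).canonicalized()
    info = {
        "em_trace": em_trace,
        "bfgs_trace": np.asarray(trace),
        "initial_objective": f0,
        "final_objective": min(float(res.fun), f0),
        "result": res,
    }
    return params, info
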