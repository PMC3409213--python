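"""Zero-mean finite Gaussian scale mixtures (GSMs) and equal-weight mixtures.

A finite GSM is a mixture of zero-mean Gaussians that share one covariance
``Sigma`` up to a scalar precision multiplier: the component at scale ``s``
has covariance ``Sigma / alpha_s``.  Larger ``alpha`` means a tighter
Gaussian.  A mixture of GSMs (MoGSM) combines several such components with
uniform prior weight ``1/(C*S)`` over all (component, scale) pairs.

These joint densities serve two roles: they are heavy-tailed models of
natural-image neighborhoods in their own right, and — fitted by EM to the
joint distribution of (neighborhood, pixel) vectors — they initialize the
training of the conditional model in :mod:`mcgsm.conditional`.

The pair (``Sigma``, ``alpha``) is only identified up to a common rescaling;
we fix the gauge by requiring ``sum_s log alpha_{cs} = 0`` per component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.special import logsumexp

__all__ = [
    "GSMParams",
    "MoGSMParams",
    "gsm_logpdf",
    "mogsm_logpdf",
    "mogsm_sample",
    "mogsm_fit_em",
]

_LOG_2PI = np.log(2.0 * np.pi)


def _validate_covariance(cov: np.ndarray, name: str = "covariance") -> np.ndarray:
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError(f"{name} must be a square matrix, got shape {cov.shape}")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    try:
        cholesky(cov, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"{name} must be positive definite") from exc
    return cov


@dataclass(frozen=True)
class GSMParams:
    """A single zero-mean finite Gaussian scale mixture.

    Parameters
    ----------
    covariance : (dim, dim) ndarray
        Shared positive-definite covariance shape.
    scales : (S,) ndarray
        Positive precision multipliers ``alpha_s``; the component at scale
        ``s`` has covariance ``covariance / alpha_s``.
    """

    covariance: np.ndarray
    scales: np.ndarray

    def __post_init__(self):
        cov = _validate_covariance(self.covariance)
        scales = np.atleast_1d(np.asarray(self.scales, dtype=float))
        if scales.ndim != 1 or scales.size < 1:
            raise ValueError("scales must be a 1-D vector with S >= 1")
        if np.any(scales <= 0):
            raise ValueError("all scales must be positive")
        object.__setattr__(self, "covariance", cov)
        object.__setattr__(self, "scales", scales)

    @property
    def dim(self) -> int:
        return self.covariance.shape[0]

    @property
    def n_scales(self) -> int:
        return self.scales.size


@dataclass(frozen=True)
class MoGSMParams:
    """Equal-weight mixture of ``C`` GSMs sharing dim and scale count."""

    components: tuple

    def __post_init__(self):
        comps = tuple(self.components)
        if len(comps) < 1:
            raise ValueError("need at least one component")
        dim = comps[0].dim
        S = comps[0].n_scales
        for g in comps:
            if g.dim != dim or g.n_scales != S:
                raise ValueError("all components must share dim and scale count")
        object.__setattr__(self, "components", comps)

    @property
    def dim(self) -> int:
        return self.components[0].dim

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def n_scales(self) -> int:
        return self.components[0].n_scales

    def covariances(self) -> np.ndarray:
        return np.stack([g.covariance for g in self.components])

    def scales(self) -> np.ndarray:
        return np.stack([g.scales for g in self.components])


def _component_scale_logpdfs(X: np.ndarray, covs: np.ndarray, alphas: np.ndarray) -> np.ndarray:
    """Log N(x; 0, Sigma_c / alpha_{cs}) for every row of X.

    Returns an (n, C, S) array.  Uses one Cholesky per component.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, dim = X.shape
    C, S = alphas.shape
    out = np.empty((n, C, S))
    for c in range(C):
        L = cholesky(covs[c], lower=True)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        z = solve_triangular(L, X.T, lower=True)
        quad = np.einsum("ij,ij->j", z, z)  # x^T Sigma_c^{-1} x
        # log N = -dim/2 log 2pi + dim/2 log a - 1/2 logdet - a/2 quad
        out[:, c, :] = (
            -0.5 * dim * _LOG_2PI
            - 0.5 * logdet
            + 0.5 * dim * np.log(alphas[c])[None, :]
            - 0.5 * quad[:, None] * alphas[c][None, :]
        )
    return out


def gsm_logpdf(x: np.ndarray, params: GSMParams) -> float | np.ndarray:
    """Log density of a finite GSM (uniform weights over scales)."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    lp = _component_scale_logpdfs(x, params.covariance[None], params.scales[None])
    out = logsumexp(lp[:, 0, :], axis=1) - np.log(params.n_scales)
    return float(out[0]) if single else out


def mogsm_logpdf(x: np.ndarray, params: MoGSMParams) -> float | np.ndarray:
    """Log density of an equal-weight mixture of GSMs; batched over rows."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != params.dim:
        raise ValueError(f"expected dim {params.dim}, got {X.shape[1]}")
    lp = _component_scale_logpdfs(X, params.covariances(), params.scales())
    out = logsumexp(lp.reshape(X.shape[0], -1), axis=1) - np.log(
        params.n_components * params.n_scales
    )
    return float(out[0]) if single else out


def mogsm_sample(params: MoGSMParams, n: int, seed) -> np.ndarray:
    """Ancestral sampling: uniform (c, s) choice, then a Gaussian draw."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    C, S, dim = params.n_components, params.n_scales, params.dim
    idx = rng.integers(C * S, size=n)
    eps = rng.standard_normal((n, dim))
    chols = np.stack([cholesky(g.covariance, lower=True) for g in params.components])
    alphas = params.scales()
    c, s = np.divmod(idx, S)
    out = np.einsum("nij,nj->ni", chols[c], eps) / np.sqrt(alphas[c, s])[:, None]
    return out


def _gauge_normalize(covs: np.ndarray, alphas: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Enforce sum_s log alpha_{cs} = 0 by moving the geometric mean into Sigma."""
    g = np.exp(np.mean(np.log(alphas), axis=1))  # (C,)
    return covs / g[:, None, None], alphas / g[:, None]


def mogsm_fit_em(
    data: np.ndarray,
    C: int,
    S: int,
    seed=0,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> tuple[MoGSMParams, np.ndarray]:
    """Fit an equal-weight zero-mean MoGSM by expectation maximization.

    The M-step is a conditional-maximization cycle: scales are updated first
    using the current component covariances,

        alpha_{cs} <- dim * sum_i r_{csi} / sum_i r_{csi} x_i^T Sigma_c^{-1} x_i,

    then covariances using the new scales,

        Sigma_c <- sum_{s,i} r_{csi} alpha_{cs} x_i x_i^T / sum_{s,i} r_{csi}.

    Each step increases the expected complete-data log-likelihood, so the
    returned trace of average log-likelihoods is non-decreasing (up to tol).
    After each iteration the scale gauge is renormalized.

    Returns
    -------
    (MoGSMParams, trace) where trace[t] is the average log-likelihood of the
    parameters at the start of iteration t.
    """
    X = np.asarray(data, dtype=float)
    n, dim = X.shape
    if n < dim:
        raise ValueError(f"need n >= dim, got n={n}, dim={dim}")
    if C < 1 or S < 1:
        raise ValueError("C and S must be >= 1")
    rng = np.random.default_rng(seed)

    # init: covariances = data second moment + seeded diagonal jitter,
    # scales log-spaced with seeded jitter to break symmetry.
    M = X.T @ X / n
    scale_floor = 1e-9 * np.trace(M) / dim
    covs = np.stack(
        [M + np.diag(np.full(dim, np.trace(M) / dim) * 0.05 * rng.uniform(0.5, 1.5, dim))
         for _ in range(C)]
    )
    if S > 1:
        base = np.linspace(-np.log(4.0), np.log(4.0), S)
    else:
        base = np.zeros(1)
    alphas = np.exp(base[None, :] + 0.1 * rng.standard_normal((C, S)))
    covs, alphas = _gauge_normalize(covs, alphas)

    trace = []
    prev = -np.inf
    for _ in range(max_iter):
        lp = _component_scale_logpdfs(X, covs, alphas)  # (n, C, S)
        lse = logsumexp(lp.reshape(n, -1), axis=1)
        avg_ll = float(np.mean(lse) - np.log(C * S))
        trace.append(avg_ll)
        r = np.exp(lp - lse[:, None, None])  # responsibilities, sum_cs = 1

        for c in range(C):
            try:
                cf = cho_factor(covs[c], lower=True)
            except np.linalg.LinAlgError:
                cf = cho_factor(covs[c] + scale_floor * np.eye(dim), lower=True)
            quad = np.einsum("ni,ni->n", X, cho_solve(cf, X.T).T)
            rc = r[:, c, :]  # (n, S)
            Rcs = rc.sum(axis=0)  # (S,)
            denom = rc.T @ quad  # (S,)
            ok = (Rcs > 1e-12) & (denom > 1e-300)
            alphas[c, ok] = dim * Rcs[ok] / denom[ok]
            w = rc @ alphas[c]  # (n,) sum_s r_csi alpha_cs
            covs[c] = (X.T * w) @ X / max(Rcs.sum(), 1e-300)
        covs, alphas = _gauge_normalize(covs, alphas)

        if np.isfinite(prev) and avg_ll - prev < tol * max(1.0, abs(prev)):
            break
        prev = avg_ll

    comps = tuple(GSMParams(covariance=covs[c], scales=alphas[c]) for c in range(C))
    return MoGSMParams(components=comps), np.asarray(trace)
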