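"""Information-theoretic model evaluation.

The central quantity is the cross-MIR: a model-based lower bound on the
multi-information rate (MIR) of a stationary image process,

    cross-MIR = h(marginal) - cross-entropy rate,

where the cross-entropy rate is the expected negative log model density of
a pixel given its causal neighborhood (estimated on held-out data) and the
marginal differential entropy is estimated nonparametrically from pixel
samples.  The MIR measures all second- and higher-order redundancy per
pixel; any model gives a lower bound, and better models give larger values.

For the multiscale factorization, per-level conditional cross-entropies
(bits per coefficient) are combined into a whole-image rate with the
coefficient-count weights 3/4^s per AC level and 1/4^L for the coarse
model.

Diagnostics from the same toolbox: phase scrambling (destroys higher-order
structure while preserving the amplitude spectrum and hence the
autocorrelation) and the Lp-spherical exponent of whitened pairs of
derivative-of-Gaussian filter responses at increasing separation, a
sensitive probe of long-range higher-order dependence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.signal import fftconvolve
from scipy.special import digamma, gammaln, polygamma
from scipy.stats import differential_entropy

from .causal import CausalMask, extract_pairs
from .conditional import MCGSMParams, conditional_logpdf, train, TrainOptions
from .multiscale import extract_superpixel_pairs, haar_analyze

__all__ = [
    "RateReport",
    "LpFit",
    "conditional_cross_entropy",
    "marginal_entropy",
    "combine_rates",
    "cross_mir",
    "evaluate_causal_model",
    "evaluate_multiscale_model",
    "nested_family_comparison",
    "scale_invariance_profile",
    "phase_scramble",
    "filter_pair_statistic",
    "fit_lp",
]

_LOG2 = np.log(2.0)


@dataclass(frozen=True)
class RateReport:
    """Cross-entropy rates and the cross-MIR, all in bits.

    ``per_scale`` rows are (scale index, bits per coefficient, coefficient
    count, variance-correction term in bits or None).  ``combined_rate`` is
    bits per original pixel; ``cross_mir = marginal_entropy - combined_rate``.
    """

    per_scale: tuple
    combined_rate: float
    marginal_entropy: float
    cross_mir: float
    sem: float

    def __post_init__(self):
        if not np.isclose(self.cross_mir, self.marginal_entropy - self.combined_rate):
            raise ValueError("cross_mir must equal marginal_entropy - combined_rate")


@dataclass(frozen=True)
class LpFit:
    """Maximum-likelihood Lp-spherical fit with a Gamma radial distribution."""

    p: float
    radial_shape: float
    radial_scale: float
    loglik: float

    def __post_init__(self):
        if self.p <= 0 or self.radial_shape <= 0 or self.radial_scale <= 0:
            raise ValueError("p and Gamma parameters must be positive")


def conditional_cross_entropy(
    model: MCGSMParams,
    Y: np.ndarray,
    X: np.ndarray,
    n_splits: int = 10,
) -> tuple[float, float]:
    """Held-out conditional cross-entropy in bits per coefficient, with SEM.

    The point estimate is the overall mean of -log2 p(x|y); the SEM is the
    sample standard deviation of the per-split means over ``n_splits``
    contiguous splits of the data (one s.d. of the estimate across test
    sets).
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if len(Y) == 0:
        raise ValueError("empty held-out set")
    bits = -conditional_logpdf(X, Y, model) / _LOG2
    est = float(np.mean(bits))
    k = min(n_splits, len(bits))
    if k >= 2:
        means = [float(np.mean(chunk)) for chunk in np.array_split(bits, k)]
        sem = float(np.std(means, ddof=1))
    else:
        sem = float("nan")
    return est, sem


def marginal_entropy(samples: np.ndarray, m_spacing: int | None = None) -> float:
    """Vasicek m-spacing estimate of differential entropy, in bits.

    Default window is round(sqrt(n)).  Degenerate (constant) samples have
    no finite differential entropy and raise.
    """
    x = np.asarray(samples, dtype=float).ravel()
    n = x.size
    if n < 100:
        raise ValueError(f"need at least 100 samples, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) samples: differential entropy is -inf")
    m = int(round(np.sqrt(n))) if m_spacing is None else int(m_spacing)
    h_nats = differential_entropy(x, window_length=m, method="vasicek")
    return float(h_nats) / _LOG2


def combine_rates(coarse_rate: float, ac_rates) -> float:
    """Whole-image bits/pixel from per-level rates.

    ``ac_rates[s-1]`` is the bits-per-AC-coefficient rate at level s
    (s = 1 finest); ``coarse_rate`` is bits/pixel of the coarse model at
    level L.  Each level contributes 3 of the 4 coefficients of a
    superpixel, so the convex weights are 3/4^s and 1/4^L:

        rate = sum_s (3/4**s) * ac_rates[s-1] + coarse_rate / 4**L
    """
    ac_rates = list(ac_rates)
    L = len(ac_rates)
    total = sum(3.0 / 4 ** (s + 1) * r for s, r in enumerate(ac_rates))
    return total + float(coarse_rate) / 4**L


def cross_mir(
    marginal_entropy_bits: float,
    combined_rate_bits: float,
    per_scale: tuple = (),
    sem: float = float("nan"),
) -> RateReport:
    """Assemble a rate report; cross-MIR = marginal entropy - combined rate.

    Negative values are allowed (a model worse than the independent
    marginal gives a negative lower bound).
    """
    return RateReport(
        per_scale=tuple(per_scale),
        combined_rate=float(combined_rate_bits),
        marginal_entropy=float(marginal_entropy_bits),
        cross_mir=float(marginal_entropy_bits) - float(combined_rate_bits),
        sem=float(sem),
    )


def evaluate_causal_model(
    model: MCGSMParams,
    mask: CausalMask,
    test_images,
    n_splits: int = 10,
    max_entropy_samples: int = 500_000,
    seed=0,
) -> RateReport:
    """Cross-MIR of a single-scale causal model on held-out images."""
    Ys, Xs, pixels = [], [], []
    for img in test_images:
        Y, X = extract_pairs(img, mask)
        Ys.append(Y)
        Xs.append(X)
        pixels.append(np.asarray(img, dtype=float).ravel())
    Y = np.concatenate(Ys)
    X = np.concatenate(Xs)
    rate, sem = conditional_cross_entropy(model, Y, X, n_splits=n_splits)
    pix = np.concatenate(pixels)
    if pix.size > max_entropy_samples:
        rng = np.random.default_rng(seed)
        pix = rng.choice(pix, size=max_entropy_samples, replace=False)
    h = marginal_entropy(pix)
    return cross_mir(h, rate, per_scale=((0, rate, len(Y), None),), sem=sem)


def evaluate_multiscale_model(
    model,
    test_images,
    n_splits: int = 10,
    max_entropy_samples: int = 500_000,
    seed=0,
) -> RateReport:
    """Cross-MIR of a multiscale model on held-out images.

    Per-level AC cross-entropies (bits per coefficient) and the coarse
    model's bits/pixel are combined with :func:`combine_rates`; the marginal
    entropy is estimated from the original-resolution pixels.
    """
    from .multiscale import _dc_chain

    L = model.levels
    per_scale = []
    ac_rates = []
    sems = []
    for lvl in range(1, L + 1):
        Ys, Xs = [], []
        for img in test_images:
            sps, _ = _dc_chain(img, lvl)
            Y, X = extract_superpixel_pairs(sps[-1], model.neighborhood)
            Ys.append(Y)
            Xs.append(X)
        rate, sem = conditional_cross_entropy(
            model.ac_models[lvl - 1], np.concatenate(Ys), np.concatenate(Xs), n_splits=n_splits
        )
        ac_rates.append(rate / 3.0)
        sems.append(sem / 3.0)
        per_scale.append((lvl, rate / 3.0, sum(len(y) for y in Ys) * 3, None))
    Ys, Xs = [], []
    for img in test_images:
        _, dc = _dc_chain(img, L)
        Y, X = extract_pairs(dc, model.coarse_mask)
        Ys.append(Y)
        Xs.append(X)
    coarse_rate, coarse_sem = conditional_cross_entropy(
        model.coarse_model, np.concatenate(Ys), np.concatenate(Xs), n_splits=n_splits
    )
    per_scale.append((L, coarse_rate, sum(len(y) for y in Ys), None))
    combined = combine_rates(coarse_rate, ac_rates)
    # combine per-level SEMs with the same convex weights
    weights = [3.0 / 4 ** (s + 1) for s in range(L)] + [1.0 / 4**L]
    sem = float(np.sqrt(sum((w * s) ** 2 for w, s in zip(weights, sems + [coarse_sem]))))
    pix = np.concatenate([np.asarray(im, float).ravel() for im in test_images])
    if pix.size > max_entropy_samples:
        rng = np.random.default_rng(seed)
        pix = rng.choice(pix, size=max_entropy_samples, replace=False)
    h = marginal_entropy(pix)
    return cross_mir(h, combined, per_scale=tuple(per_scale), sem=sem)


_NESTED_FAMILIES = {
    "CG": (1, 1),
    "MCG": (3, 1),
    "CGSM": (1, 3),
    "MCGSM": (3, 2),
}


def nested_family_comparison(
    train_images,
    test_images,
    k: int = 5,
    L: int = 2,
    N: int = 3,
    n_samples: int = 40_000,
    families: dict | None = None,
    include_multiscale: bool = True,
    seed=0,
    opts: TrainOptions | None = None,
) -> dict:
    """Cross-MIR of the nested single-scale families and the multiscale model.

    The single-scale families are special cases of the MCGSM: conditional
    Gaussian CG (C=S=1), zero-mean mixture of conditional Gaussians MCG
    (S=1), conditional GSM (C=1), and the full MCGSM; the multiscale model
    stacks MCGSMs over the Haar pyramid.  Each is trained on pooled causal
    pairs from ``train_images`` and scored on ``test_images``.  Component
    counts are deliberately small; the comparison probes the ranking, not
    absolute performance.
    """
    families = dict(_NESTED_FAMILIES if families is None else families)
    from .causal import make_causal_mask

    rng = np.random.default_rng(seed)
    mask = make_causal_mask(k)
    opts = opts or TrainOptions(max_iter=300, em_max_iter=30, n_init=2)
    Y, X = _pooled_pairs(train_images, mask, n_samples, rng)
    reports: dict[str, RateReport] = {}
    for name, (C, S) in families.items():
        model, _ = train(Y, X, C=C, S=S, seed=int(rng.integers(2**31)), opts=opts)
        reports[name] = evaluate_causal_model(
            model, mask, test_images, seed=int(rng.integers(2**31))
        )
    if include_multiscale:
        from .multiscale import train_multiscale

        C, S = families.get("MCGSM", (3, 2))
        ms = train_multiscale(
            train_images, L=L, N=N, C=C, S=S, coarse_k=k,
            n_samples=n_samples, seed=int(rng.integers(2**31)), opts=opts,
        )
        reports["MCGSM+multiscale"] = evaluate_multiscale_model(
            ms, test_images, seed=int(rng.integers(2**31))
        )
    return reports


def scale_invariance_profile(
    train_images,
    test_images,
    L: int,
    C: int = 2,
    S: int = 2,
    k: int = 5,
    N: int = 3,
    n_samples: int = 20_000,
    n_splits: int = 10,
    seed=0,
    opts: TrainOptions | None = None,
) -> dict:
    """Per-scale information rates of an image corpus.

    For every scale s = 0..L the images are block-averaged s times (Haar DC
    chain) and an identical-architecture single-scale causal MCGSM is
    trained and evaluated, giving a per-scale cross-MIR profile.  For
    scales 1..L an AC-predictor MCGSM is trained on the superpixel pairs of
    that level, giving per-scale conditional cross-entropies of the AC
    3-vector; the reported correction term 3*log2(kappa_s) (kappa_s
    equalizing the per-coefficient standard deviation to scale 1) makes
    them comparable across scales for a scale-invariant process.
    """
    from .causal import make_causal_mask

    rng = np.random.default_rng(seed)
    mask = make_causal_mask(k)

    def dc_chain(img, s):
        cur = np.asarray(img, dtype=float)
        sps = []
        for _ in range(s):
            sp = haar_analyze(cur)
            sps.append(sp)
            cur = sp[..., 0]
        return sps, cur

    mirs = []
    for s in range(L + 1):
        tr = [dc_chain(im, s)[1] for im in train_images]
        te = [dc_chain(im, s)[1] for im in test_images]
        Y, X = _pooled_pairs(tr, mask, n_samples, rng)
        model, _ = train(Y, X, C=C, S=S, seed=int(rng.integers(2**31)), opts=opts)
        rep = evaluate_causal_model(model, mask, te, n_splits=n_splits, seed=int(rng.integers(2**31)))
        mirs.append((s, rep.cross_mir, rep.sem))

    ac_entropies = []
    sd_ref = None
    for s in range(1, L + 1):
        tr_sp = [dc_chain(im, s)[0][-1] for im in train_images]
        te_sp = [dc_chain(im, s)[0][-1] for im in test_images]
        Ys, Xs = [], []
        for sp in tr_sp:
            Yi, Xi = extract_superpixel_pairs(sp, N)
            Ys.append(Yi)
            Xs.append(Xi)
        Y, X = np.concatenate(Ys), np.concatenate(Xs)
        if len(Y) > n_samples:
            sel = rng.choice(len(Y), size=n_samples, replace=False)
            Y, X = Y[sel], X[sel]
        model, _ = train(Y, X, C=C, S=S, seed=int(rng.integers(2**31)), opts=opts)
        Yt, Xt = [], []
        for sp in te_sp:
            Yi, Xi = extract_superpixel_pairs(sp, N)
            Yt.append(Yi)
            Xt.append(Xi)
        Yt, Xt = np.concatenate(Yt), np.concatenate(Xt)
        rate, sem = conditional_cross_entropy(model, Yt, Xt, n_splits=n_splits)
        sd = float(np.std(Xt))
        if sd_ref is None:
            sd_ref = sd
        kappa = sd_ref / sd
        # rate is bits per AC 3-vector coefficient? conditional_cross_entropy
        # scores the 3-vector jointly; report per coefficient.
        ac_entropies.append((s, rate / 3.0, sem / 3.0, np.log2(kappa)))

    return {"per_scale_mir": mirs, "per_scale_ac_entropy": ac_entropies}


def _pooled_pairs(images, mask, n_samples, rng):
    Ys, Xs = [], []
    for img in images:
        Y, X = extract_pairs(img, mask)
        Ys.append(Y)
        Xs.append(X)
    Y = np.concatenate(Ys)
    X = np.concatenate(Xs)
    if len(Y) > n_samples:
        sel = rng.choice(len(Y), size=n_samples, replace=False)
        Y, X = Y[sel], X[sel]
    return Y, X


def phase_scramble(image: np.ndarray, seed=0) -> np.ndarray:
    """Replace the phase spectrum with that of a white-noise image.

    The amplitude spectrum — and with it the autocorrelation function — is
    preserved exactly; all higher-order correlations are destroyed.  The DC
    coefficient of the original is retained so the mean is unchanged.
    """
    img = np.asarray(image, dtype=float)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(img.shape)
    F = np.fft.fft2(img)
    Fn = np.fft.fft2(noise)
    phases = np.exp(1j * np.angle(Fn))
    out = np.abs(F) * phases
    out.flat[0] = F.flat[0]
    return np.real(np.fft.ifft2(out))


def _dog_kernel(sigma: float) -> np.ndarray:
    """Vertically oriented derivative-of-Gaussian filter, zero-sum, unit L2."""
    r = int(np.ceil(4 * sigma))
    y = np.arange(-r, r + 1)[:, None]
    x = np.arange(-r, r + 1)[None, :]
    k = -y * np.exp(-(x * x + y * y) / (2 * sigma * sigma))
    k -= k.mean()
    return k / np.sqrt(np.sum(k * k))


def _symmetric_whiten(pairs: np.ndarray) -> np.ndarray:
    cov = np.cov(pairs.T)
    vals, vecs = np.linalg.eigh(cov)
    W = vecs @ np.diag(1.0 / np.sqrt(np.maximum(vals, 1e-300))) @ vecs.T
    return pairs @ W.T


def filter_pair_statistic(
    images,
    offsets,
    filter_sigma: float = 1.5,
    max_pairs: int = 200_000,
    seed=0,
    min_pairs: int = 1000,
) -> list[tuple[int, LpFit]]:
    """Lp exponent of whitened derivative-filter response pairs vs offset.

    Each image is convolved with a vertical derivative-of-Gaussian kernel;
    responses at vertical separation d are paired, whitened with the
    symmetric inverse square root of their 2x2 covariance, and fitted with
    an Lp-spherical/Gamma-radial model.  Returns [(d, LpFit), ...].
    """
    rng = np.random.default_rng(seed)
    kernel = _dog_kernel(filter_sigma)
    responses = [fftconvolve(np.asarray(im, dtype=float), kernel, mode="valid") for im in images]
    out = []
    for d in offsets:
        pairs = []
        for resp in responses:
            if resp.shape[0] <= d:
                continue
            a = resp[:-d or None, :] if d > 0 else resp
            b = resp[d:, :]
            pairs.append(np.stack([a.ravel(), b.ravel()], axis=1))
        if not pairs:
            raise ValueError(f"no image tall enough for offset {d}")
        P = np.concatenate(pairs)
        if len(P) < min_pairs:
            raise ValueError(f"only {len(P)} response pairs at offset {d}")
        if len(P) > max_pairs:
            P = P[rng.choice(len(P), size=max_pairs, replace=False)]
        out.append((int(d), fit_lp(_symmetric_whiten(P))))
    return out


def _gamma_mle(r: np.ndarray) -> tuple[float, float, float]:
    """Gamma shape/scale MLE via Newton on the shape; returns (shape, scale, ll)."""
    mean = float(np.mean(r))
    meanlog = float(np.mean(np.log(r)))
    s = np.log(mean) - meanlog
    shape = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    for _ in range(50):
        num = np.log(shape) - digamma(shape) - s
        den = 1.0 / shape - polygamma(1, shape)
        step = num / den
        new = shape - step
        if new <= 0:
            new = shape / 2.0
        if abs(new - shape) < 1e-12 * shape:
            shape = new
            break
        shape = new
    scale = mean / shape
    n = r.size
    ll = float(
        (shape - 1.0) * np.sum(np.log(r))
        - np.sum(r) / scale
        - n * (gammaln(shape) + shape * np.log(scale))
    )
    return float(shape), float(scale), ll


def _lp_ball_log_volume(p: float) -> float:
    """log volume of the 2-D unit Lp ball: 4*Gamma(1+1/p)^2 / Gamma(1+2/p)."""
    return np.log(4.0) + 2.0 * gammaln(1.0 + 1.0 / p) - gammaln(1.0 + 2.0 / p)


def fit_lp(pairs: np.ndarray, p_bounds: tuple[float, float] = (0.1, 4.0)) -> LpFit:
    """Maximum-likelihood 2-D Lp-spherical fit with Gamma radial density.

    The density of x with radius r = ||x||_p distributed as g is

        f(x) = g(r) / (2 * V_p * r),

    V_p being the 2-D unit-Lp-ball volume; the profile log-likelihood over
    the Gamma radial parameters is maximized by bounded search over p.
    """
    P = np.asarray(pairs, dtype=float)
    if P.ndim != 2 or P.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array")
    n = len(P)
    if n < 100:
        raise ValueError("need at least 100 pairs")
    absP = np.abs(P)
    absP = np.maximum(absP, 1e-300)

    def profile_nll(p):
        r = (absP[:, 0] ** p + absP[:, 1] ** p) ** (1.0 / p)
        _, _, ll_r = _gamma_mle(r)
        ll = ll_r - np.sum(np.log(r)) - n * (np.log(2.0) + _lp_ball_log_volume(p))
        return -ll

    res = minimize_scalar(
        profile_nll, bounds=p_bounds, method="bounded", options={"xatol": 1e-4}
    )
    if not res.success:
        raise RuntimeError(f"Lp profile-likelihood search failed: {res}")
    p_hat = float(res.x)
    r = (absP[:, 0] ** p_hat + absP[:, 1] ** p_hat) ** (1.0 / p_hat)
    shape, scale, _ = _gamma_mle(r)
    return LpFit(p=p_hat, radial_shape=shape, radial_scale=scale, loglik=float(-res.fun))
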