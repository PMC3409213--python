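"""Haar superpixel representation and the coarse-to-fine generative model.

Each 2x2 pixel block is transformed with the orthonormal Haar basis into a
four-channel "superpixel": one DC (block-average up to scaling) channel and
three AC detail channels (horizontal, vertical, diagonal).  Because the
basis is orthonormal the transform has Jacobian determinant 1, so
likelihoods in the transformed representation equal likelihoods of the
original image with no correction term.

The multiscale model factorizes an image coarse-to-fine: a single-scale
causal MCGSM generates the coarsest DC image, and at each finer level one
MCGSM predicts the three AC channels of a superpixel from the full (not
causal) DC window plus the causal halves of the three AC channels.  The DC
channel may be accessed non-causally because, during generation, the entire
low-resolution image is already known before any details are sampled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .causal import CausalMask, extract_pairs, image_loglik, make_causal_mask, sample_image
from .conditional import (
    MCGSMParams,
    TrainOptions,
    conditional_logpdf,
    conditional_sample,
    train,
)

__all__ = [
    "haar_analyze",
    "haar_synthesize",
    "build_features",
    "extract_superpixel_pairs",
    "MultiscaleModel",
    "train_multiscale",
    "sample_multiscale",
    "multiscale_loglik",
    "MultiscaleLoglik",
]

_LOG2 = np.log(2.0)


def haar_analyze(image: np.ndarray) -> np.ndarray:
    """Orthonormal 2x2 Haar transform to a (H/2, W/2, 4) superpixel image.

    For a block [[a, b], [c, d]] the channels are
    DC = (a+b+c+d)/2, AC_h = (a-b+c-d)/2, AC_v = (a+b-c-d)/2,
    AC_d = (a-b-c+d)/2; the transform preserves the sum of squares.
    """
    img = np.asarray(image, dtype=float)
    H, W = img.shape
    if H % 2 or W % 2:
        raise ValueError(f"image dimensions must be even, got {img.shape}")
    a = img[0::2, 0::2]
    b = img[0::2, 1::2]
    c = img[1::2, 0::2]
    d = img[1::2, 1::2]
    return 0.5 * np.stack([a + b + c + d, a - b + c - d, a + b - c - d, a - b - c + d], axis=-1)


def haar_synthesize(sp: np.ndarray) -> np.ndarray:
    """Exact inverse of :func:`haar_analyze` (the basis is self-inverse)."""
    sp = np.asarray(sp, dtype=float)
    if sp.ndim != 3 or sp.shape[2] != 4:
        raise ValueError("expected a (H, W, 4) superpixel array")
    dc, h, v, g = sp[..., 0], sp[..., 1], sp[..., 2], sp[..., 3]
    H, W = sp.shape[:2]
    out = np.empty((2 * H, 2 * W))
    out[0::2, 0::2] = 0.5 * (dc + h + v + g)
    out[0::2, 1::2] = 0.5 * (dc - h + v - g)
    out[1::2, 0::2] = 0.5 * (dc + h - v - g)
    out[1::2, 1::2] = 0.5 * (dc - h - v + g)
    return out


def _causal_offsets(N: int) -> list[tuple[int, int]]:
    return list(make_causal_mask(N).offsets)


def feature_dim(N: int) -> int:
    """Input dimension of an AC predictor: full DC window + 3 causal AC halves."""
    return N * N + 3 * (N * N - 1) // 2


def build_features(sp: np.ndarray, location: tuple[int, int], N: int) -> tuple[np.ndarray, np.ndarray]:
    """Feature/target vectors for one superpixel location.

    y concatenates the DC channel over the full N x N window centered at
    ``location`` (row-major) with the three AC channels over the causal half
    of the window; x is the AC 3-vector at ``location``.
    """
    if N % 2 == 0 or N < 3:
        raise ValueError("N must be odd and >= 3")
    i, j = location
    h = (N - 1) // 2
    H, W = sp.shape[:2]
    if not (h <= i < H - h and h <= j < W - h):
        raise ValueError(f"location {location} too close to the boundary for N={N}")
    dc_win = sp[i - h:i + h + 1, j - h:j + h + 1, 0].ravel()
    offs = _causal_offsets(N)
    ac = np.array([sp[i + r, j + c, 1:4] for r, c in offs])  # (n_off, 3)
    y = np.concatenate([dc_win, ac.T.ravel()])  # channel-major AC ordering
    x = sp[i, j, 1:4].copy()
    return y, x


def extract_superpixel_pairs(
    sp: np.ndarray,
    N: int,
    n_max: int | None = None,
    seed=0,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`build_features` over all interior locations."""
    if N % 2 == 0 or N < 3:
        raise ValueError("N must be odd and >= 3")
    h = (N - 1) // 2
    H, W = sp.shape[:2]
    if H < N or W < N:
        raise ValueError(f"superpixel image {sp.shape[:2]} smaller than window {N}")
    rows = np.arange(h, H - h)
    cols = np.arange(h, W - h)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    rr, cc = rr.ravel(), cc.ravel()
    if n_max is not None and n_max < rr.size:
        rng = np.random.default_rng(seed)
        sel = rng.choice(rr.size, size=n_max, replace=False)
        rr, cc = rr[sel], cc[sel]
    win = [(r, c) for r in range(-h, h + 1) for c in range(-h, h + 1)]
    wr = np.array([r for r, _ in win])
    wc = np.array([c for _, c in win])
    Ydc = sp[rr[:, None] + wr[None, :], cc[:, None] + wc[None, :], 0]
    offs = _causal_offsets(N)
    orr = np.array([r for r, _ in offs])
    occ = np.array([c for _, c in offs])
    Yac = sp[rr[:, None] + orr[None, :], cc[:, None] + occ[None, :], 1:4]  # (n, off, 3)
    Yac = np.swapaxes(Yac, 1, 2).reshape(len(rr), -1)  # channel-major
    Y = np.concatenate([Ydc, Yac], axis=1)
    X = sp[rr, cc, 1:4]
    return Y, X


@dataclass(frozen=True)
class MultiscaleModel:
    """Coarse single-scale MCGSM plus one AC-predictor MCGSM per finer level.

    ``ac_models[0]`` is the finest level (the first Haar analysis of the
    original image); ``coarse_model`` acts on the DC image after ``levels``
    analysis steps.
    """

    coarse_model: MCGSMParams
    coarse_mask: CausalMask
    ac_models: tuple
    neighborhood: int  # N, superpixel window size of the AC predictors

    def __post_init__(self):
        object.__setattr__(self, "ac_models", tuple(self.ac_models))
        m = feature_dim(self.neighborhood)
        for lvl, mdl in enumerate(self.ac_models):
            if mdl.in_dim != m or mdl.out_dim != 3:
                raise ValueError(f"AC model at level {lvl + 1} has wrong dimensions")
        if self.coarse_model.out_dim != 1 or self.coarse_model.in_dim != len(self.coarse_mask):
            raise ValueError("coarse model does not match its causal mask")

    @property
    def levels(self) -> int:
        return len(self.ac_models)


def _dc_chain(image: np.ndarray, L: int) -> tuple[list[np.ndarray], np.ndarray]:
    """Superpixel images at levels 1..L and the final DC image."""
    sps = []
    cur = np.asarray(image, dtype=float)
    for _ in range(L):
        sp = haar_analyze(cur)
        sps.append(sp)
        cur = sp[..., 0]
    return sps, cur


def train_multiscale(
    images: Sequence[np.ndarray],
    L: int,
    N: int = 3,
    C: int = 8,
    S: int = 4,
    coarse_k: int = 7,
    n_samples: int = 100_000,
    seed=0,
    opts: TrainOptions | None = None,
) -> MultiscaleModel:
    """Train the multiscale model on a corpus of images.

    One AC-predictor MCGSM is trained per level on pooled superpixel pairs
    (a seeded subsample of at most ``n_samples``), plus the single-scale
    coarse model on the L-times downsampled DC images.
    """
    rng = np.random.default_rng(seed)
    coarse_mask = make_causal_mask(coarse_k)
    per_level: list[list] = [[] for _ in range(L)]
    dc_images = []
    for img in images:
        sps, dc = _dc_chain(img, L)
        for lvl, sp in enumerate(sps):
            per_level[lvl].append(sp)
        dc_images.append(dc)

    ac_models = []
    for lvl in range(L):
        Ys, Xs = [], []
        for sp in per_level[lvl]:
            try:
                Y, X = extract_superpixel_pairs(sp, N)
            except ValueError as exc:
                raise ValueError(f"images too small for level {lvl + 1}: {exc}") from exc
            Ys.append(Y)
            Xs.append(X)
        Y = np.concatenate(Ys)
        X = np.concatenate(Xs)
        if len(Y) > n_samples:
            sel = rng.choice(len(Y), size=n_samples, replace=False)
            Y, X = Y[sel], X[sel]
        params, _ = train(Y, X, C=C, S=S, seed=int(rng.integers(2**31)), opts=opts)
        ac_models.append(params)

    Ys, Xs = [], []
    for dc in dc_images:
        try:
            Y, X = extract_pairs(dc, coarse_mask)
        except ValueError as exc:
            raise ValueError(f"DC images too small for the coarse model: {exc}") from exc
        Ys.append(Y)
        Xs.append(X)
    Y = np.concatenate(Ys)
    X = np.concatenate(Xs)
    if len(Y) > n_samples:
        sel = rng.choice(len(Y), size=n_samples, replace=False)
        Y, X = Y[sel], X[sel]
    coarse, _ = train(Y, X, C=C, S=S, seed=int(rng.integers(2**31)), opts=opts)
    return MultiscaleModel(
        coarse_model=coarse, coarse_mask=coarse_mask, ac_models=tuple(ac_models), neighborhood=N
    )


def sample_multiscale(
    model: MultiscaleModel,
    coarse_shape: tuple[int, int],
    seed=0,
    burn_rows: int = 16,
    boundary: float = 0.1,
    return_coarse: bool = False,
) -> np.ndarray:
    """Sample an image coarse-to-fine; output side = coarse side * 2^levels.

    The coarse image is raster-sampled (on an enlarged canvas that is
    burned in and cropped to ``coarse_shape``), then at each finer level the
    AC channels are raster-sampled given the full DC window and causal AC
    neighborhoods, and the level is synthesized.  AC coefficients in the
    window margin are left at zero.  Analyzing the output ``levels`` times
    recovers the coarse sample exactly (returned too with
    ``return_coarse``).
    """
    rng = np.random.default_rng(seed)
    h, w = coarse_shape
    pad_shape = (h + 2 * burn_rows, w + 2 * burn_rows)
    img = sample_image(
        model.coarse_model, model.coarse_mask, pad_shape,
        boundary=boundary, burn_rows=burn_rows, seed=rng,
    )
    coarse_img = img
    N = model.neighborhood
    half = (N - 1) // 2
    for lvl in range(model.levels - 1, -1, -1):
        mdl = model.ac_models[lvl]
        H, W = img.shape
        sp = np.zeros((H, W, 4))
        sp[..., 0] = img
        for i in range(half, H - half):
            for j in range(half, W - half):
                y, _ = build_features(sp, (i, j), N)
                sp[i, j, 1:4] = conditional_sample(y, mdl, rng)
        img = haar_synthesize(sp)
    if return_coarse:
        return img, coarse_img
    return img


class MultiscaleLoglik(NamedTuple):
    total: float       # nats over all scored coefficients
    coarse: object     # ImageLoglik of the coarse DC image
    per_level: tuple   # (level, loglik_nats, n_locations)


def multiscale_loglik(image: np.ndarray, model: MultiscaleModel) -> MultiscaleLoglik:
    """Whole-image log-likelihood under the coarse-to-fine factorization.

    Because the Haar transform is orthonormal, the likelihood of the
    transformed coefficients equals the likelihood of the image — no
    Jacobian term.  Margins (boundary pixels of the coarse model, window
    margins of the AC predictors) are excluded; counts are reported.
    """
    img = np.asarray(image, dtype=float)
    L = model.levels
    if any(sz % (2**L) for sz in img.shape):
        raise ValueError(f"image shape {img.shape} not divisible by 2^{L}")
    sps, dc = _dc_chain(img, L)
    per_level = []
    total = 0.0
    for lvl, sp in enumerate(sps):
        Y, X = extract_superpixel_pairs(sp, model.neighborhood)
        ll = conditional_logpdf(X, Y, model.ac_models[lvl])
        per_level.append((lvl + 1, float(np.sum(ll)), len(ll)))
        total += float(np.sum(ll))
    coarse = image_loglik(dc, model.coarse_model, model.coarse_mask)
    total += coarse.total
    return MultiscaleLoglik(total=total, coarse=coarse, per_level=tuple(per_level))
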