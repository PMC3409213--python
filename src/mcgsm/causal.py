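"""Stationary directed (causal-neighborhood) image model.

An image is factorized pixel by pixel in raster order: each pixel is
conditioned on a fixed set of already-visited neighbors (above it, or left
of it in the same row).  One shared conditional density — here an MCGSM —
then defines an exact whole-image likelihood and a raster-scan sampler.
Pixels whose neighborhood sticks out of the image are treated as boundary:
they are excluded from the likelihood and initialized (typically with small
white noise) before sampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.linalg import cholesky

from .conditional import MCGSMParams, conditional_logpdf

__all__ = [
    "CausalMask",
    "make_causal_mask",
    "extract_pairs",
    "image_loglik",
    "sample_image",
    "ImageLoglik",
]

_LOG2 = np.log(2.0)


@dataclass(frozen=True)
class CausalMask:
    """Ordered set of strictly causal (row, col) offsets.

    Offsets are relative to the predicted pixel and must satisfy row < 0, or
    row == 0 and col < 0.  Ordering is row-major so feature vectors are
    reproducible.
    """

    offsets: tuple

    def __post_init__(self):
        offs = [(int(r), int(c)) for r, c in self.offsets]
        if len(set(offs)) != len(offs):
            raise ValueError("offsets must be unique")
        for r, c in offs:
            if not (r < 0 or (r == 0 and c < 0)):
                raise ValueError(f"offset {(r, c)} is not causal")
        object.__setattr__(self, "offsets", tuple(sorted(offs)))

    def __len__(self) -> int:
        return len(self.offsets)

    @property
    def extents(self) -> tuple[int, int, int]:
        """(rows_above, cols_left, cols_right) reach of the mask."""
        rows = [-r for r, _ in self.offsets]
        lefts = [-c for _, c in self.offsets if c < 0]
        rights = [c for _, c in self.offsets if c > 0]
        return (max(rows, default=0), max(lefts, default=0), max(rights, default=0))

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        off = np.asarray(self.offsets, dtype=int)
        return off[:, 0], off[:, 1]


def make_causal_mask(size: int) -> CausalMask:
    """Upper half of a ``size`` x ``size`` window around the predicted pixel.

    All full-width rows above the pixel plus the pixels to its left in the
    same row; size must be odd.  size=7 gives the 24-pixel neighborhood.
    """
    k = int(size)
    if k % 2 == 0 or k < 3:
        raise ValueError(f"window size must be odd and >= 3, got {k}")
    h = (k - 1) // 2
    offsets = [(r, c) for r in range(-h, 0) for c in range(-h, h + 1)]
    offsets += [(0, c) for c in range(-h, 0)]
    return CausalMask(offsets=tuple(offsets))


def _interior_slices(shape: tuple[int, int], mask: CausalMask):
    H, W = shape
    above, left, right = mask.extents
    if H <= above or W <= left + right:
        raise ValueError(
            f"image of shape {shape} too small for mask extents {(above, left, right)}"
        )
    return range(above, H), range(left, W - right)


def extract_pairs(
    image: np.ndarray,
    mask: CausalMask,
    n_max: int | None = None,
    seed=0,
) -> tuple[np.ndarray, np.ndarray]:
    """Neighborhood/pixel training pairs from every interior pixel.

    Returns (Y, X): Y[n, m] holds the neighborhood values in mask order and
    X[n, 1] the predicted pixel.  With ``n_max`` set, a seeded subsample of
    interior pixels is used.
    """
    img = np.asarray(image, dtype=float)
    rows, cols = _interior_slices(img.shape, mask)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    rr, cc = rr.ravel(), cc.ravel()
    if n_max is not None and n_max < rr.size:
        rng = np.random.default_rng(seed)
        sel = rng.choice(rr.size, size=n_max, replace=False)
        rr, cc = rr[sel], cc[sel]
    dr, dc = mask.arrays()
    Y = img[rr[:, None] + dr[None, :], cc[:, None] + dc[None, :]]
    X = img[rr, cc][:, None]
    return Y, X


class ImageLoglik(NamedTuple):
    total: float          # nats, summed over interior pixels
    rate_bits: float      # bits per interior pixel
    n_pixels: int         # interior pixel count
    n_boundary: int       # excluded boundary pixel count


def image_loglik(image: np.ndarray, model: MCGSMParams, mask: CausalMask) -> ImageLoglik:
    """Exact log-likelihood of the interior of an image under the causal model."""
    if model.in_dim != len(mask) or model.out_dim != 1:
        raise ValueError(
            f"model dims (m={model.in_dim}, d={model.out_dim}) do not match "
            f"mask size {len(mask)} / scalar pixel"
        )
    img = np.asarray(image, dtype=float)
    Y, X = extract_pairs(img, mask)
    ll = conditional_logpdf(X, Y, model)
    total = float(np.sum(ll))
    n = len(ll)
    return ImageLoglik(
        total=total,
        rate_bits=-total / n / _LOG2,
        n_pixels=n,
        n_boundary=img.size - n,
    )


def sample_image(
    model: MCGSMParams,
    mask: CausalMask,
    shape: tuple[int, int],
    boundary: float | np.ndarray = 0.1,
    burn_rows: int = 32,
    seed=0,
) -> np.ndarray:
    """Raster-scan sampling of an image from the causal model.

    The margins (and initially the whole canvas) are filled from ``boundary``
    — either a white-noise standard deviation or a full-canvas image — then
    each interior pixel is sampled left-to-right, top-to-bottom from the
    conditional density.  A frame of ``burn_rows`` rows/columns is cropped
    from every side so the returned sample comes from the (converged)
    stationary part of the scan.
    """
    if model.out_dim != 1 or model.in_dim != len(mask):
        raise ValueError("model must be scalar-output and match the mask size")
    H, W = shape
    above, left, right = mask.extents
    if H <= 2 * burn_rows + above or W <= 2 * burn_rows + left + right:
        raise ValueError("shape must exceed mask extents plus burn-in margins")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if np.isscalar(boundary):
        img = float(boundary) * rng.standard_normal((H, W))
    else:
        img = np.array(boundary, dtype=float)
        if img.shape != (H, W):
            raise ValueError("boundary image must match the requested shape")

    dr, dc = mask.arrays()
    C, S = model.n_components, model.n_scales
    m = model.in_dim
    logdetK = np.array(
        [2.0 * np.sum(np.log(np.diag(cholesky(model.K[c], lower=True)))) for c in range(C)]
    )
    sig = np.array([np.sqrt(float(model.Sigma[c][0, 0])) for c in range(C)])
    a_row = model.A[:, 0, :]  # (C, m)
    la = np.log(model.alphas)
    base = 0.5 * m * la + 0.5 * logdetK[:, None]  # (C, S)

    for i in range(above, H):
        ri = i + dr
        for j in range(left, W - right):
            y = img[ri, j + dc]
            quad = np.einsum("cij,i,j->c", model.K, y, y)
            g = base - 0.5 * quad[:, None] * model.alphas
            gf = g.ravel()
            gf -= gf.max()
            w = np.exp(gf)
            w /= w.sum()
            idx = int(np.searchsorted(np.cumsum(w), rng.random()))
            idx = min(idx, C * S - 1)
            c, s = divmod(idx, S)
            mean = float(a_row[c] @ y)
            img[i, j] = mean + sig[c] / np.sqrt(model.alphas[c, s]) * rng.standard_normal()
    if burn_rows > 0:
        img = img[burn_rows:H - burn_rows, burn_rows:W - burn_rows]
    return img
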