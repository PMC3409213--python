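"""Synthetic image and sample generators with known statistical structure.

Everything the modeling and evaluation pipeline assumes can be produced
here without external data: dead-leaves occlusion images (power-law disk
sizes, optional additive Gaussian noise), separable AR(1) images whose
multi-information rate is known in closed form, corpora sampled from a
known generative model, and Lp-spherically distributed response pairs with
a Gamma radial law.

All generators are pure functions of (configuration, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .causal import CausalMask, sample_image
from .conditional import MCGSMParams
from .multiscale import MultiscaleModel, sample_multiscale

__all__ = [
    "DeadLeavesConfig",
    "dead_leaves",
    "ar_image",
    "ar1_mir_bits",
    "known_model_corpus",
    "lp_pairs",
]


@dataclass(frozen=True)
class DeadLeavesConfig:
    """Configuration of the dead-leaves occlusion simulator.

    Disks with radius density proportional to ``r**-size_exponent`` on
    [r_min, r_max] and i.i.d. intensities occlude one another until the
    canvas is covered; ``noise_sigma`` of white Gaussian noise is added at
    the end (occlusion images without noise have infinite differential
    information rates).  Centers are drawn on a canvas extended by ``r_max``
    on every side so the visible region is stationary.
    """

    size: tuple[int, int] = (128, 128)
    r_min: float = 1.0
    r_max: float = 32.0
    size_exponent: float = 3.0
    noise_sigma: float = 0.01
    seed: int = 0
    intensity_quantiles: np.ndarray | None = None  # optional custom law; None = uniform(0,1)

    def __post_init__(self):
        if not (0 < self.r_min < self.r_max):
            raise ValueError("need 0 < r_min < r_max")
        if self.size_exponent <= 1:
            raise ValueError("size_exponent must exceed 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.r_max < 0.5:
            raise ValueError("r_max < 0.5 px cannot cover any pixel")


def sample_radii(config: DeadLeavesConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF radius draws for density proportional to r**-exponent."""
    e = config.size_exponent - 1.0  # CDF involves r**-(e)
    a = config.r_min ** -e
    b = config.r_max ** -e
    u = rng.random(n)
    return (a - u * (a - b)) ** (-1.0 / e)


def dead_leaves(config: DeadLeavesConfig) -> np.ndarray:
    """One dead-leaves image: disks painted front-to-back onto uncovered pixels.

    Painting each new disk only where no earlier disk is present is the
    front-to-back equivalent of the classical back-to-front occlusion
    process, but terminates as soon as every pixel is covered.
    """
    rng = np.random.default_rng(config.seed)
    H, W = config.size
    margin = int(np.ceil(config.r_max))
    img = np.zeros((H, W))
    covered = np.zeros((H, W), dtype=bool)
    n_uncovered = H * W
    batch = 256
    while n_uncovered > 0:
        radii = sample_radii(config, batch, rng)
        cy = rng.uniform(-margin, H + margin, batch)
        cx = rng.uniform(-margin, W + margin, batch)
        u = rng.random(batch)
        if config.intensity_quantiles is not None:
            q = np.asarray(config.intensity_quantiles, dtype=float)
            colors = np.interp(u, np.linspace(0, 1, len(q)), q)
        else:
            colors = u
        for r, y0, x0, col in zip(radii, cy, cx, colors):
            lo_y = max(int(np.floor(y0 - r)), 0)
            hi_y = min(int(np.ceil(y0 + r)) + 1, H)
            lo_x = max(int(np.floor(x0 - r)), 0)
            hi_x = min(int(np.ceil(x0 + r)) + 1, W)
            if lo_y >= hi_y or lo_x >= hi_x:
                continue
            yy = np.arange(lo_y, hi_y)[:, None] - y0
            xx = np.arange(lo_x, hi_x)[None, :] - x0
            disk = yy * yy + xx * xx <= r * r
            patch = covered[lo_y:hi_y, lo_x:hi_x]
            paint = disk & ~patch
            if paint.any():
                img[lo_y:hi_y, lo_x:hi_x][paint] = col
                patch |= disk
                n_uncovered -= int(paint.sum())
            if n_uncovered == 0:
                break
    if config.noise_sigma > 0:
        img = img + config.noise_sigma * rng.standard_normal((H, W))
    return img


def ar_image(shape: tuple[int, int], rho: float, seed=0) -> np.ndarray:
    """Rows are independent stationary AR(1) processes with unit innovations.

    The per-pixel multi-information rate of this process is
    ``-0.5 * log2(1 - rho**2)`` (see :func:`ar1_mir_bits`).
    """
    if not -1.0 < rho < 1.0:
        raise ValueError(f"|rho| must be < 1, got {rho}")
    rng = np.random.default_rng(seed)
    H, W = shape
    out = np.empty((H, W))
    out[:, 0] = rng.standard_normal(H) / np.sqrt(1.0 - rho * rho)
    eps = rng.standard_normal((H, W - 1))
    for j in range(1, W):
        out[:, j] = rho * out[:, j - 1] + eps[:, j - 1]
    return out


def ar1_mir_bits(rho: float) -> float:
    """Closed-form multi-information rate of the row-AR(1) process, bits/pixel."""
    return -0.5 * np.log2(1.0 - rho * rho)


def known_model_corpus(
    model: MCGSMParams | MultiscaleModel,
    n_images: int,
    shape: tuple[int, int],
    seed=0,
    mask: CausalMask | None = None,
    **sample_kwargs,
) -> list[np.ndarray]:
    """Corpus of images sampled from a known generator with derived seeds.

    For a single-scale :class:`MCGSMParams`, ``mask`` is required and
    ``shape`` is the sampled canvas before burn-in cropping; for a
    :class:`MultiscaleModel`, ``shape`` is the coarse resolution.
    """
    root = np.random.default_rng(seed)
    seeds = root.integers(2**31, size=n_images)
    images = []
    for s in seeds:
        if isinstance(model, MultiscaleModel):
            images.append(sample_multiscale(model, shape, seed=int(s), **sample_kwargs))
        else:
            if mask is None:
                raise ValueError("mask is required for single-scale models")
            images.append(sample_image(model, mask, shape, seed=int(s), **sample_kwargs))
    return images


def lp_pairs(p: float, radial_shape: float, radial_scale: float, n: int, seed=0) -> np.ndarray:
    """Samples from a 2-D Lp-spherical density with Gamma radial law.

    Direction is uniform on the Lp unit sphere (normalized signed
    generalized-Gaussian draws of exponent p), radius is
    Gamma(radial_shape, radial_scale); rows are radius * direction.
    """
    if p <= 0:
        raise ValueError("p must be positive")
    rng = np.random.default_rng(seed)
    g = rng.gamma(1.0 / p, 1.0, size=(n, 2)) ** (1.0 / p)
    g *= rng.choice([-1.0, 1.0], size=(n, 2))
    norm = (np.abs(g) ** p).sum(axis=1) ** (1.0 / p)
    u = g / norm[:, None]
    r = rng.gamma(radial_shape, radial_scale, size=n)
    return r[:, None] * u
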