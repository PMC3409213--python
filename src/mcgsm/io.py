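"""Image and model I/O, preprocessing, and corpus bookkeeping.

Images travel either as integer raster formats (PGM/PNG/TIFF, converted to
float64 on load) or as ``.npy`` float arrays, which round-trip losslessly
and are the native container for model-space (e.g. log-luminance) images.
Models are stored in versioned HDF5 containers with bit-exact array
round-trips.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np

from .causal import CausalMask
from .conditional import MCGSMParams
from .multiscale import MultiscaleModel

__all__ = [
    "load_image",
    "save_image",
    "log_transform",
    "load_van_hateren",
    "save_model",
    "load_model",
    "CorpusManifest",
    "make_manifest",
]

_MODEL_VERSION = 1
_INT_FORMATS = {".pgm", ".png", ".tif", ".tiff"}


def load_image(path) -> np.ndarray:
    """Load an image as a float64 array; ``.npy`` is read back bit-exactly."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    if path.suffix == ".npy":
        arr = np.load(path)
    elif path.suffix.lower() in _INT_FORMATS:
        arr = np.asarray(iio.imread(path))
        if arr.ndim != 2:
            raise ValueError(f"{path}: expected a grayscale image, got shape {arr.shape}")
    else:
        raise ValueError(f"{path}: unsupported image format '{path.suffix}'")
    return np.asarray(arr, dtype=float)


def save_image(image: np.ndarray, path) -> None:
    """Save an image; ``.npy`` is lossless, integer formats round to 16 bits."""
    path = Path(path)
    img = np.asarray(image, dtype=float)
    if path.suffix == ".npy":
        np.save(path, img)
    elif path.suffix.lower() in _INT_FORMATS:
        lo, hi = float(img.min()), float(img.max())
        scale = 65535.0 / (hi - lo) if hi > lo else 1.0
        iio.imwrite(path, np.round((img - lo) * scale).astype(np.uint16))
    else:
        raise ValueError(f"{path}: unsupported image format '{path.suffix}'")


def log_transform(image: np.ndarray, offset: float = 0.0) -> np.ndarray:
    """Natural log of (image + offset); all entries must end up positive."""
    img = np.asarray(image, dtype=float)
    shifted = img + offset
    bad = int(np.count_nonzero(shifted <= 0))
    if bad:
        raise ValueError(f"{bad} entries are non-positive after offset {offset}")
    return np.log(shifted)


def load_van_hateren(path, shape: tuple[int, int] = (1024, 1536)) -> np.ndarray:
    """Reader for the raw 16-bit big-endian .iml/.imc camera format.

    The dataset itself is external and never downloaded by this package.
    """
    raw = np.fromfile(path, dtype=">u2")
    expected = shape[0] * shape[1]
    if raw.size != expected:
        raise ValueError(f"{path}: expected {expected} pixels, found {raw.size}")
    return raw.reshape(shape).astype(float)


def _write_mcgsm(grp: h5py.Group, params: MCGSMParams) -> None:
    grp.create_dataset("K", data=params.K)
    grp.create_dataset("alphas", data=params.alphas)
    grp.create_dataset("A", data=params.A)
    grp.create_dataset("Sigma", data=params.Sigma)


def _read_mcgsm(grp: h5py.Group) -> MCGSMParams:
    return MCGSMParams(
        K=grp["K"][...], alphas=grp["alphas"][...], A=grp["A"][...], Sigma=grp["Sigma"][...]
    )


def save_model(model: MCGSMParams | MultiscaleModel, path, mask: CausalMask | None = None) -> None:
    """Serialize a model to a versioned HDF5 container (bit-exact round trip).

    Single-scale models may bundle their causal mask; multiscale models
    always store their masks and window sizes.
    """
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = _MODEL_VERSION
        if isinstance(model, MultiscaleModel):
            f.attrs["kind"] = "multiscale"
            f.attrs["neighborhood"] = model.neighborhood
            f.create_dataset("coarse_mask", data=np.asarray(model.coarse_mask.offsets))
            _write_mcgsm(f.create_group("coarse"), model.coarse_model)
            f.attrs["levels"] = model.levels
            for lvl, mdl in enumerate(model.ac_models):
                _write_mcgsm(f.create_group(f"ac_{lvl + 1}"), mdl)
        else:
            f.attrs["kind"] = "mcgsm"
            _write_mcgsm(f.create_group("params"), model)
            if mask is not None:
                f.create_dataset("mask", data=np.asarray(mask.offsets))


def load_model(path):
    """Load a model container; returns (MCGSMParams, mask-or-None) or MultiscaleModel."""
    path = Path(path)
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise OSError(f"cannot read model container {path}: {exc}") from exc
    with f:
        version = int(f.attrs.get("format_version", -1))
        if version != _MODEL_VERSION:
            raise ValueError(
                f"{path}: unsupported model format version {version} "
                f"(expected {_MODEL_VERSION})"
            )
        kind = f.attrs["kind"]
        if kind == "multiscale":
            coarse = _read_mcgsm(f["coarse"])
            mask = CausalMask(offsets=tuple(map(tuple, f["coarse_mask"][...])))
            L = int(f.attrs["levels"])
            ac = tuple(_read_mcgsm(f[f"ac_{lvl + 1}"]) for lvl in range(L))
            return MultiscaleModel(
                coarse_model=coarse,
                coarse_mask=mask,
                ac_models=ac,
                neighborhood=int(f.attrs["neighborhood"]),
            )
        params = _read_mcgsm(f["params"])
        mask = None
        if "mask" in f:
            mask = CausalMask(offsets=tuple(map(tuple, f["mask"][...])))
        return params, mask


@dataclass(frozen=True)
class CorpusManifest:
    """Paths, preprocessing tag and seed-stable train/test split of a corpus."""

    train: tuple
    test: tuple
    preprocessing: str
    split_seed: int

    def __post_init__(self):
        if set(self.train) & set(self.test):
            raise ValueError("train and test sets must be disjoint")

    def to_json(self) -> str:
        return json.dumps(
            {
                "train": [str(p) for p in self.train],
                "test": [str(p) for p in self.test],
                "preprocessing": self.preprocessing,
                "split_seed": self.split_seed,
            },
            indent=2,
        )


def make_manifest(
    paths, test_fraction: float = 0.2, preprocessing: str = "raw", seed: int = 0
) -> CorpusManifest:
    """Seed-stable disjoint train/test split over a list of image paths."""
    paths = [str(p) for p in paths]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(paths))
    n_test = max(1, int(round(test_fraction * len(paths)))) if len(paths) > 1 else 0
    test = tuple(paths[i] for i in order[:n_test])
    trainset = tuple(paths[i] for i in order[n_test:])
    return CorpusManifest(train=trainset, test=test, preprocessing=preprocessing, split_seed=seed)
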