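"""HRME preprocessing chain: size standardization, de-combing, CLAHE.

Raw fiber-bundle images carry a honeycomb ("comb") artifact from the discrete
fiber cores.  The standard preprocessing applied before any analysis is:
standardize to 960×1280 px, remove the comb with a Gaussian filter of sigma
2 px, then enhance contrast with CLAHE at a normalized clip limit of 0.005.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.exposure import equalize_adapthist

__all__ = [
    "PreprocessConfig",
    "standardize_size",
    "gaussian_decomb",
    "clahe",
    "preprocess_image",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing parameters.

    ``clahe_clip_limit`` follows the normalized convention: the fraction of a
    tile's pixel count at which its histogram is clipped.
    """

    target_height_px: int = 960
    target_width_px: int = 1280
    gaussian_sigma_px: float = 2.0
    clahe_clip_limit: float = 0.005
    clahe_tile_grid: tuple[int, int] = (8, 8)

    def __post_init__(self) -> None:
        if self.target_height_px <= 0 or self.target_width_px <= 0:
            raise ValueError("target size must be positive")
        if self.gaussian_sigma_px < 0:
            raise ValueError("gaussian_sigma_px must be nonnegative")
        if not 0.0 < self.clahe_clip_limit <= 1.0:
            raise ValueError("clahe_clip_limit must lie in (0, 1]")
        if any(t <= 0 for t in self.clahe_tile_grid):
            raise ValueError("tile grid entries must be positive")

    def to_dict(self) -> dict:
        return {
            "target_height_px": self.target_height_px,
            "target_width_px": self.target_width_px,
            "gaussian_sigma_px": self.gaussian_sigma_px,
            "clahe_clip_limit": self.clahe_clip_limit,
            "clahe_tile_grid": list(self.clahe_tile_grid),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessConfig":
        d = dict(d)
        if "clahe_tile_grid" in d:
            d["clahe_tile_grid"] = tuple(d["clahe_tile_grid"])
        return cls(**d)


def standardize_size(
    image: np.ndarray, cfg: PreprocessConfig | None = None
) -> np.ndarray:
    """Force an image to the standard frame by center-crop / reflect-pad.

    Cropping and symmetric (edge-inclusive) reflection padding leave
    intensity values untouched, unlike resampling, so the µm-per-pixel
    geometry the degradation model relies on is preserved.
    """
    cfg = cfg or PreprocessConfig()
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("image must be nonempty")
    th, tw = cfg.target_height_px, cfg.target_width_px

    out = image
    for axis, target in ((0, th), (1, tw)):
        size = out.shape[axis]
        if size > target:
            start = (size - target) // 2
            sl = [slice(None)] * out.ndim
            sl[axis] = slice(start, start + target)
            out = out[tuple(sl)]
        elif size < target:
            missing = target - size
            before = missing // 2
            after = missing - before
            pad = [(0, 0)] * out.ndim
            pad[axis] = (before, after)
            out = np.pad(out, pad, mode="symmetric")
    return out


def gaussian_decomb(image: np.ndarray, sigma_px: float = 2.0) -> np.ndarray:
    """Suppress the comb pattern with a 2-D Gaussian low-pass filter.

    Reflect boundary handling with a normalized kernel truncated at 4 sigma;
    this is linear and preserves the global mean.  ``sigma_px = 0`` is the
    identity.
    """
    if sigma_px < 0:
        raise ValueError("sigma_px must be nonnegative")
    image = np.asarray(image, dtype=float)
    if sigma_px == 0:
        return image.copy()
    return gaussian_filter(image, sigma_px, mode="reflect", truncate=4.0)


def clahe(
    image: np.ndarray,
    clip_limit: float = 0.005,
    tile_grid: tuple[int, int] = (8, 8),
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on a [0, 1] image.

    Tile-wise clipped-histogram equalization with bilinear interpolation
    between tile mappings; ``clip_limit`` is the normalized histogram
    clipping fraction.
    """
    if not 0.0 < clip_limit <= 1.0:
        raise ValueError("clip_limit must lie in (0, 1]")
    image = np.asarray(image, dtype=float)
    if image.min() < 0 or image.max() > 1:
        raise ValueError("image must lie in [0, 1]")
    h, w = image.shape
    kernel = (max(1, int(np.ceil(h / tile_grid[0]))),
              max(1, int(np.ceil(w / tile_grid[1]))))
    return equalize_adapthist(image, kernel_size=kernel, clip_limit=clip_limit)


def preprocess_image(
    image: np.ndarray, cfg: PreprocessConfig | None = None
) -> np.ndarray:
    """Full chain: standardize size → Gaussian de-comb → CLAHE."""
    cfg = cfg or PreprocessConfig()
    out = standardize_size(image, cfg)
    out = gaussian_decomb(out, cfg.gaussian_sigma_px)
    out = clahe(out, cfg.clahe_clip_limit, cfg.clahe_tile_grid)
    return out
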