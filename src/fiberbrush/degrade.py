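"""Sparse "brush" acquisition model for an end-expandable fiber probe.

An end-expandable probe spreads unfused fiber strands over the tissue, so
each strand samples only a small region-of-interest (ROI) of the wider
field-of-view (FOV) tile it is responsible for.  The degradation model tiles
the high-resolution image into s×s-pixel FOV blocks, centers an m×m-pixel ROI
in each block, optionally displaces the ROI by a random per-block deformation
offset of at most d pixels per axis (strand flexibility), and replaces the
whole FOV block with the mean intensity over the (clipped) ROI.  The result
is the reconstituted low-resolution (LR) image a camera would register
through such a probe.

Geometry is parameterized in microns and converted at ``pixel_size_um``
(default 2 µm/px, i.e. a 4 µm fiber core covers 2 px).  Tiling is rectangular
and anchored at pixel (0, 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "DegradationParams",
    "SparseAcquisition",
    "to_pixel_params",
    "sample_offsets",
    "degrade",
    "interpolate_sparse",
]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class DegradationParams:
    """Fiber-probe geometry: core diameter m, inter-fiber distance s,
    maximum deformation offset d, all in microns."""

    m_um: float = 4.0
    s_um: float = 8.0
    d_um: float = 0.0
    pixel_size_um: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not 0 < self.m_um <= self.s_um:
            raise ValueError("require 0 < m_um <= s_um")
        if self.d_um < 0:
            raise ValueError("d_um must be nonnegative")


@dataclass
class SparseAcquisition:
    """The sparse brush sample and its reconstituted LR image.

    ``sparse_values`` holds the per-fiber mean on the ROI footprint (pixels
    outside any ROI are 0 and excluded by ``mask``); ``offsets`` is the
    per-block (dy, dx) table; ``lr_image`` is block-constant.
    """

    sparse_values: np.ndarray
    mask: np.ndarray
    offsets: np.ndarray
    lr_image: np.ndarray
    params: DegradationParams


def to_pixel_params(p: DegradationParams) -> tuple[int, int, int]:
    """Convert (m, s, d) from microns to whole pixels, rounding half-up."""
    m_px = _round_half_up(p.m_um / p.pixel_size_um)
    s_px = _round_half_up(p.s_um / p.pixel_size_um)
    d_px = _round_half_up(p.d_um / p.pixel_size_um)
    if m_px < 1:
        raise ValueError("fiber diameter is below one pixel")
    s_px = max(s_px, m_px)  # rounding must not violate m <= s
    return m_px, s_px, d_px


def sample_offsets(
    n_blocks_y: int,
    n_blocks_x: int,
    d_px: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-block integer deformation offsets, shape (ny, nx, 2).

    Each axis is independent discrete-uniform on {-d_px, ..., +d_px} — the
    simplest distribution consistent with a stated maximum displacement.
    """
    if d_px < 0:
        raise ValueError("d_px must be nonnegative")
    if d_px == 0:
        return np.zeros((n_blocks_y, n_blocks_x, 2), dtype=np.int64)
    return rng.integers(
        -d_px, d_px + 1, size=(n_blocks_y, n_blocks_x, 2), dtype=np.int64
    )


def degrade(
    hr: np.ndarray,
    p: DegradationParams,
    offsets: np.ndarray | None = None,
) -> SparseAcquisition:
    """Simulate sparse brush acquisition of a high-resolution image.

    The image is tiled into s_px × s_px FOV blocks anchored at (0, 0); edge
    blocks of non-divisible dimensions are processed on their clipped
    extents.  Within each block an m_px × m_px ROI with top-left corner at
    floor((s_px - m_px)/2) is shifted by the block's offset, intersected with
    the image bounds, and its mean fills the entire FOV block.

    ``offsets`` overrides the seeded random table (useful for enumeration and
    for freezing one probe configuration across a dataset).
    """
    hr = np.asarray(hr, dtype=float)
    if hr.ndim != 2:
        raise ValueError("hr must be a 2-D grayscale image")
    if hr.min() < 0 or hr.max() > 1:
        raise ValueError("hr must lie in [0, 1]")
    m_px, s_px, d_px = to_pixel_params(p)
    h, w = hr.shape
    if s_px > h or s_px > w:
        raise ValueError("inter-fiber distance exceeds the image dimensions")

    ny = -(-h // s_px)
    nx = -(-w // s_px)
    if offsets is None:
        rng = np.random.default_rng(p.seed)
        offsets = sample_offsets(ny, nx, d_px, rng)
    else:
        offsets = np.asarray(offsets, dtype=np.int64)
        if offsets.shape != (ny, nx, 2):
            raise ValueError(
                f"offsets table must have shape {(ny, nx, 2)}, "
                f"got {offsets.shape}"
            )

    lr = np.empty_like(hr)
    sparse = np.zeros_like(hr)
    mask = np.zeros(hr.shape, dtype=bool)
    margin = (s_px - m_px) // 2

    for by in range(ny):
        b_y0 = by * s_px
        b_y1 = min(b_y0 + s_px, h)
        for bx in range(nx):
            b_x0 = bx * s_px
            b_x1 = min(b_x0 + s_px, w)
            dy, dx = offsets[by, bx]
            r_y0 = b_y0 + margin + int(dy)
            r_x0 = b_x0 + margin + int(dx)
            r_y1 = min(r_y0 + m_px, h)
            r_x1 = min(r_x0 + m_px, w)
            r_y0 = max(r_y0, 0)
            r_x0 = max(r_x0, 0)
            if r_y0 >= r_y1 or r_x0 >= r_x1:
                # offset pushed the ROI fully outside: fall back to the
                # clipped unshifted ROI so the fiber always reports a value
                r_y0 = max(min(b_y0 + margin, h - 1), 0)
                r_x0 = max(min(b_x0 + margin, w - 1), 0)
                r_y1 = min(r_y0 + m_px, h)
                r_x1 = min(r_x0 + m_px, w)
            value = hr[r_y0:r_y1, r_x0:r_x1].mean()
            lr[b_y0:b_y1, b_x0:b_x1] = value
            sparse[r_y0:r_y1, r_x0:r_x1] = value
            mask[r_y0:r_y1, r_x0:r_x1] = True

    return SparseAcquisition(
        sparse_values=sparse, mask=mask, offsets=offsets, lr_image=lr,
        params=p,
    )


def interpolate_sparse(
    sparse: SparseAcquisition, method: str = "block_fill"
) -> np.ndarray:
    """Reconstitute a full image from the sparse acquisition.

    ``block_fill`` (the probe's native reconstitution) reproduces
    ``lr_image`` exactly.  ``bilinear`` interpolates between FOV block
    centers and is a smoother baseline for comparison only.
    """
    if not sparse.mask.any():
        raise ValueError("sparse acquisition has an empty mask")
    if method == "block_fill":
        return sparse.lr_image.copy()
    if method != "bilinear":
        raise ValueError(f"unknown interpolation method {method!r}")

    p = sparse.params
    _, s_px, _ = to_pixel_params(p)
    h, w = sparse.lr_image.shape
    ny, nx = sparse.offsets.shape[:2]
    # block centers (edge blocks may be clipped, use their true extents)
    cy = np.array(
        [(by * s_px + min((by + 1) * s_px, h) - 1) / 2.0 for by in range(ny)]
    )
    cx = np.array(
        [(bx * s_px + min((bx + 1) * s_px, w) - 1) / 2.0 for bx in range(nx)]
    )
    vals = sparse.lr_image[
        np.clip(np.round(cy).astype(int), 0, h - 1)[:, None],
        np.clip(np.round(cx).astype(int), 0, w - 1)[None, :],
    ]
    interp = RegularGridInterpolator(
        (cy, cx), vals, method="linear", bounds_error=False, fill_value=None
    )
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
    # clamp to the convex hull of block centers (constant extrapolation)
    pts[:, 0] = np.clip(pts[:, 0], cy[0], cy[-1])
    pts[:, 1] = np.clip(pts[:, 1], cx[0], cx[-1])
    return interp(pts).reshape(h, w)
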