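"""Synthetic microendoscopy phantoms.

High-resolution microendoscopy (HRME) of proflavine-stained epithelium shows
bright nuclei on a dim cytoplasmic background; nuclear density, size and
pleomorphism are the visual cues that separate neoplastic from non-neoplastic
mucosa.  This module generates labeled grayscale phantoms with that
statistical structure — a homogeneous spatial Poisson process of anti-aliased
elliptical nuclei plus Gaussian sensor noise — so the downstream degradation,
super-resolution and reader-statistics stages can be exercised without
clinical data.

All images are float64 rasters in [0, 1]; geometry is specified in microns and
converted through ``pixel_size_um`` (2 µm/px by default).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse as _draw_ellipse

__all__ = [
    "PhantomSpec",
    "CombPatternSpec",
    "LabeledImage",
    "PRESETS",
    "sample_nuclei",
    "generate_phantom",
    "apply_comb_pattern",
    "generate_dataset",
    "write_dataset",
]

#: Edge smoothing of rendered nuclei, in pixels.
NUCLEUS_EDGE_SIGMA_PX = 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic HRME-like image.

    Intensities are fractions of the dynamic range; lengths are microns.
    ``nucleus_density_per_mm2`` is the intensity of the spatial Poisson
    process that places nucleus centers.
    """

    height_px: int = 960
    width_px: int = 1280
    pixel_size_um: float = 2.0
    nucleus_density_per_mm2: float = 150.0
    nucleus_radius_mean_um: float = 4.0
    nucleus_radius_sd_um: float = 0.8
    nucleus_eccentricity_max: float = 0.6
    nucleus_intensity: float = 0.85
    background_intensity: float = 0.25
    noise_sd: float = 0.02
    class_label: str = "non_neoplastic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height_px <= 0 or self.width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.nucleus_density_per_mm2 < 0:
            raise ValueError("nucleus density must be nonnegative")
        for name in ("nucleus_intensity", "background_intensity", "noise_sd"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.nucleus_intensity <= self.background_intensity:
            raise ValueError(
                "nucleus_intensity must exceed background_intensity "
                "(nuclei are stained bright)"
            )
        if not 0.0 <= self.nucleus_eccentricity_max < 1.0:
            raise ValueError("nucleus_eccentricity_max must lie in [0, 1)")
        if self.class_label not in ("neoplastic", "non_neoplastic"):
            raise ValueError(f"unknown class_label {self.class_label!r}")
        radius_px = self.nucleus_radius_mean_um / self.pixel_size_um
        if radius_px > min(self.height_px, self.width_px):
            raise ValueError("field too small to hold one mean nucleus radius")

    @property
    def field_area_mm2(self) -> float:
        """Imaged area in mm² at the configured pixel size."""
        um2 = self.height_px * self.width_px * self.pixel_size_um**2
        return um2 / 1e6


@dataclass(frozen=True)
class CombPatternSpec:
    """Geometry of the fused-bundle comb (honeycomb) artifact.

    Individual fiber cores in a fused bundle are 4–6 µm across and sit on an
    approximately hexagonal lattice; each core reports one intensity and the
    cladding between cores is darker.
    """

    core_diameter_um: float = 4.0
    core_pitch_um: float = 6.0
    lattice: str = "hexagonal"
    cladding_attenuation: float = 0.5

    def __post_init__(self) -> None:
        if self.core_diameter_um <= 0 or self.core_pitch_um <= 0:
            raise ValueError("core diameter and pitch must be positive")
        if self.core_diameter_um > self.core_pitch_um:
            raise ValueError("core_diameter_um must not exceed core_pitch_um")
        if self.lattice != "hexagonal":
            raise ValueError("only the hexagonal lattice is supported")
        if not 0.0 <= self.cladding_attenuation <= 1.0:
            raise ValueError("cladding_attenuation must lie in [0, 1]")


@dataclass
class LabeledImage:
    """A grayscale image with its diagnostic label and perceptual quality."""

    image: np.ndarray
    label: str
    quality: str = "good"
    provenance: PhantomSpec | str | None = None

    def __post_init__(self) -> None:
        if self.label not in ("neoplastic", "non_neoplastic"):
            raise ValueError(f"unknown label {self.label!r}")
        if self.quality not in ("good", "intermediate"):
            raise ValueError(f"unknown quality {self.quality!r}")


# Class presets: free parameters of the phantom model, not claims about
# esophageal biology.  The neoplastic preset has higher nuclear density
# (crowding) and double the radius SD (pleomorphism).
PRESETS: dict[str, PhantomSpec] = {
    "non_neoplastic": PhantomSpec(
        nucleus_density_per_mm2=150.0,
        nucleus_radius_mean_um=4.0,
        nucleus_radius_sd_um=0.8,
        class_label="non_neoplastic",
    ),
    "neoplastic": PhantomSpec(
        nucleus_density_per_mm2=350.0,
        nucleus_radius_mean_um=5.0,
        nucleus_radius_sd_um=1.6,
        class_label="neoplastic",
    ),
}


def sample_nuclei(
    spec: PhantomSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw nucleus centers and shapes for one phantom.

    Returns ``(centers_yx_px, radii_px, eccentricities, orientations)`` where
    the number of nuclei is Poisson(density × field area) and centers are
    uniform over the field.  Radii are truncated-normal (positive), in pixels.
    Exposed separately so the placement statistics can be checked without
    rendering.
    """
    lam = spec.nucleus_density_per_mm2 * spec.field_area_mm2
    n = int(rng.poisson(lam))
    centers = np.column_stack(
        [
            rng.uniform(0.0, spec.height_px, size=n),
            rng.uniform(0.0, spec.width_px, size=n),
        ]
    )
    mean_px = spec.nucleus_radius_mean_um / spec.pixel_size_um
    sd_px = spec.nucleus_radius_sd_um / spec.pixel_size_um
    radii = rng.normal(mean_px, sd_px, size=n)
    # truncate: redraw nonpositive radii from the positive tail
    bad = radii <= 0.25
    while np.any(bad):
        radii[bad] = rng.normal(mean_px, sd_px, size=int(bad.sum()))
        bad = radii <= 0.25
    ecc = rng.uniform(0.0, spec.nucleus_eccentricity_max, size=n)
    theta = rng.uniform(0.0, np.pi, size=n)
    return centers, radii, ecc, theta


def generate_phantom(spec: PhantomSpec) -> LabeledImage:
    """Render one synthetic HRME-like image from its spec.

    Nuclei are filled ellipses (semi-axes from the sampled radius and
    eccentricity, uniform orientation) combined by maximum intensity and
    smoothed with a Gaussian of sigma 1 px; additive zero-mean Gaussian noise
    is applied last and the result is clipped to [0, 1].  Identical specs
    (including seed) yield bitwise-identical images.
    """
    rng = np.random.default_rng(spec.seed)
    centers, radii, ecc, theta = sample_nuclei(spec, rng)

    mask = np.zeros((spec.height_px, spec.width_px), dtype=float)
    for (cy, cx), r, e, th in zip(centers, radii, ecc, theta):
        # eccentricity e relates the semi-axes: minor = major * sqrt(1 - e^2),
        # with the mean radius preserved as the geometric mean
        axis_ratio = np.sqrt(1.0 - e**2)
        a = r / np.sqrt(axis_ratio)
        b = r * np.sqrt(axis_ratio)
        rr, cc = _draw_ellipse(
            cy, cx, a, b, shape=mask.shape, rotation=float(th)
        )
        mask[rr, cc] = 1.0
    if NUCLEUS_EDGE_SIGMA_PX > 0:
        mask = gaussian_filter(mask, NUCLEUS_EDGE_SIGMA_PX, mode="reflect")
        np.clip(mask, 0.0, 1.0, out=mask)

    image = spec.background_intensity + (
        spec.nucleus_intensity - spec.background_intensity
    ) * mask
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    np.clip(image, 0.0, 1.0, out=image)
    return LabeledImage(image=image, label=spec.class_label, provenance=spec)


def _hex_core_centers(
    shape: tuple[int, int], pitch_px: float
) -> np.ndarray:
    """Centers of a hexagonal lattice covering ``shape``, in pixel coords."""
    h, w = shape
    row_step = pitch_px * np.sqrt(3.0) / 2.0
    centers = []
    row = 0
    y = 0.0
    while y < h + pitch_px:
        x0 = (pitch_px / 2.0) if (row % 2) else 0.0
        x = x0
        while x < w + pitch_px:
            centers.append((y, x))
            x += pitch_px
        y += row_step
        row += 1
    return np.asarray(centers, dtype=float)


def apply_comb_pattern(image: np.ndarray, comb: CombPatternSpec,
                       pixel_size_um: float = 2.0) -> np.ndarray:
    """Imprint the fused-bundle comb artifact on an image.

    Circular cores on a hexagonal lattice are each filled with the mean of
    the underlying image inside the core; cladding pixels (outside every
    core) are multiplied by ``1 - cladding_attenuation``.
    """
    image = np.asarray(image, dtype=float)
    if image.min() < 0 or image.max() > 1:
        raise ValueError("image must lie in [0, 1]")
    pitch_px = comb.core_pitch_um / pixel_size_um
    if pitch_px < 1.0:
        raise ValueError("core pitch must be at least one pixel")
    radius_px = comb.core_diameter_um / (2.0 * pixel_size_um)

    h, w = image.shape
    yy, xx = np.mgrid[0:h, 0:w]
    centers = _hex_core_centers(image.shape, pitch_px)
    # assign each pixel to its nearest core center; pixels within radius of
    # that center are core pixels, the rest are cladding
    out = image * (1.0 - comb.cladding_attenuation)
    core_mask = np.zeros(image.shape, dtype=bool)
    r_ceil = int(np.ceil(radius_px))
    for cy, cx in centers:
        y0, y1 = int(np.floor(cy - r_ceil)), int(np.ceil(cy + r_ceil)) + 1
        x0, x1 = int(np.floor(cx - r_ceil)), int(np.ceil(cx + r_ceil)) + 1
        y0, x0 = max(y0, 0), max(x0, 0)
        y1, x1 = min(y1, h), min(x1, w)
        if y0 >= y1 or x0 >= x1:
            continue
        dy = yy[y0:y1, x0:x1] - cy
        dx = xx[y0:y1, x0:x1] - cx
        disk = dy**2 + dx**2 <= radius_px**2
        if not disk.any():
            continue
        out[y0:y1, x0:x1][disk] = image[y0:y1, x0:x1][disk].mean()
        core_mask[y0:y1, x0:x1] |= disk
    return np.clip(out, 0.0, 1.0)


def generate_dataset(
    n: int,
    neoplastic_fraction: float,
    presets: dict[str, PhantomSpec] | None = None,
    seed: int = 0,
    height_px: int | None = None,
    width_px: int | None = None,
) -> tuple[list[LabeledImage], list[dict]]:
    """Generate a labeled phantom dataset and its manifest.

    ``round(n * neoplastic_fraction)`` images use the neoplastic preset, the
    rest the non-neoplastic one; the class sequence is shuffled
    deterministically under ``seed`` and each image gets its own derived seed.
    The manifest carries one JSON-serializable record per image (index, label,
    quality, seed, full spec).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0.0 <= neoplastic_fraction <= 1.0:
        raise ValueError("neoplastic_fraction must lie in [0, 1]")
    presets = dict(PRESETS if presets is None else presets)

    n_neo = int(round(n * neoplastic_fraction))
    labels = ["neoplastic"] * n_neo + ["non_neoplastic"] * (n - n_neo)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    labels = [labels[i] for i in order]
    image_seeds = rng.integers(0, 2**31 - 1, size=n)

    images: list[LabeledImage] = []
    manifest: list[dict] = []
    for i, (label, s) in enumerate(zip(labels, image_seeds)):
        spec = presets[label]
        overrides: dict = {"seed": int(s)}
        if height_px is not None:
            overrides["height_px"] = height_px
        if width_px is not None:
            overrides["width_px"] = width_px
        spec = dataclasses.replace(spec, **overrides)
        img = generate_phantom(spec)
        images.append(img)
        manifest.append(
            {
                "index": i,
                "image_id": f"phantom_{i:04d}",
                "label": label,
                "quality": img.quality,
                "seed": int(s),
                "spec": dataclasses.asdict(spec),
            }
        )
    return images, manifest


def write_dataset(
    images: Sequence[LabeledImage],
    manifest: Iterable[dict],
    out_dir: str | Path,
    bit_depth: int = 8,
) -> Path:
    """Write images (PNG 8-bit or TIFF 16-bit) plus a JSON-lines manifest."""
    from . import imgio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = list(manifest)
    for rec, li in zip(records, images):
        ext = "png" if bit_depth == 8 else "tif"
        path = out_dir / f"{rec['image_id']}.{ext}"
        imgio.write_gray(path, li.image, bit_depth=bit_depth)
        rec["path"] = path.name
    manifest_path = out_dir / "manifest.jsonl"
    with open(manifest_path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")
    return manifest_path
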