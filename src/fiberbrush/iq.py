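"""Traditional image-quality metrics and the degradation parameter sweep.

PSNR and SSIM quantify how much the sparse-acquisition model degrades an
image and how much of that the SRCNN recovers.  ``run_sweep`` varies one
probe parameter at a time (deformation offset d, inter-fiber distance s,
fiber diameter m) around a fixed baseline, optionally retraining the SRCNN
per grid point, and tabulates LR and SR metrics — the harness used to pick
tolerable probe geometries before prototyping.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import correlate as _nd_correlate
from scipy.stats import t as _t_dist

from .degrade import DegradationParams, degrade
from . import srcnn as _srcnn

__all__ = [
    "IQResult",
    "SweepGrid",
    "psnr",
    "ssim",
    "evaluate_conditions",
    "run_sweep",
]


@dataclass(frozen=True)
class IQResult:
    """Per-image quality metrics for one condition (LR or SR)."""

    image_id: str
    psnr_db: float
    ssim: float
    condition: str
    params: DegradationParams | None = None


@dataclass(frozen=True)
class SweepGrid:
    """One-at-a-time parameter grid around a fixed baseline, in microns."""

    offsets_um: tuple[float, ...] = (0, 2, 4, 6, 8, 10)
    inter_fiber_um: tuple[float, ...] = (4, 8, 12, 16, 20, 24)
    diameters_um: tuple[float, ...] = (4, 6, 8, 10, 12)
    fixed_baseline: DegradationParams = field(
        default_factory=DegradationParams
    )


def psnr(ref: np.ndarray, test: np.ndarray, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio 10*log10(peak^2 / MSE), in dB.

    Identical images have zero MSE and return +inf.
    """
    ref = np.asarray(ref, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if ref.shape != test.shape:
        raise ValueError("ref and test must share a shape")
    if peak <= 0:
        raise ValueError("peak must be positive")
    mse = float(np.mean((ref - test) ** 2))
    if mse == 0.0:
        return np.inf
    return 10.0 * np.log10(peak**2 / mse)


def _gaussian_kernel_1d(sigma: float, radius: int) -> np.ndarray:
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def ssim(
    ref: np.ndarray,
    test: np.ndarray,
    data_range: float = 1.0,
    sigma: float = 1.5,
    k1: float = 0.01,
    k2: float = 0.03,
) -> float:
    """Mean structural similarity index over an 11x11 Gaussian window.

    Local (weighted, population) means/variances/covariance enter the
    standard luminance-contrast-structure product with stabilizers
    C1 = (k1*L)^2 and C2 = (k2*L)^2 on dynamic range L; the local map is
    averaged over the region where the window fits entirely.
    """
    ref = np.asarray(ref, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if ref.shape != test.shape:
        raise ValueError("ref and test must share a shape")
    radius = int(3.5 * sigma + 0.5)  # sigma 1.5 -> 11x11 window
    win = 2 * radius + 1
    if min(ref.shape) < win:
        raise ValueError(f"image smaller than the {win}x{win} SSIM window")
    k = _gaussian_kernel_1d(sigma, radius)
    kern = np.outer(k, k)

    def smooth(a: np.ndarray) -> np.ndarray:
        return _nd_correlate(a, kern, mode="reflect")

    mu_x = smooth(ref)
    mu_y = smooth(test)
    var_x = smooth(ref * ref) - mu_x**2
    var_y = smooth(test * test) - mu_y**2
    cov = smooth(ref * test) - mu_x * mu_y
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    s = ((2 * mu_x * mu_y + c1) * (2 * cov + c2)) / (
        (mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2)
    )
    return float(s[radius:-radius, radius:-radius].mean())


def evaluate_conditions(
    hr_set: dict[str, np.ndarray],
    lr_set: dict[str, np.ndarray],
    sr_set: dict[str, np.ndarray] | None = None,
    params: DegradationParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-image LR (and SR) metrics against HR plus condition aggregates.

    Returns ``(per_image, summary)`` DataFrames; the summary carries mean,
    SD and a t-based 95% CI of each metric per condition.  Image ids must
    align across the sets.
    """
    conditions = {"LR": lr_set}
    if sr_set is not None:
        conditions["SR"] = sr_set
    for name, s in conditions.items():
        if set(s) != set(hr_set):
            raise ValueError(f"image ids of {name} set do not match HR set")

    rows = []
    for cond, imgs in conditions.items():
        for image_id in sorted(hr_set):
            rows.append(
                {
                    "image_id": image_id,
                    "condition": cond,
                    "psnr_db": psnr(hr_set[image_id], imgs[image_id]),
                    "ssim": ssim(hr_set[image_id], imgs[image_id]),
                }
            )
    per_image = pd.DataFrame(rows)

    summaries = []
    for cond, grp in per_image.groupby("condition"):
        for metric in ("psnr_db", "ssim"):
            vals = grp[metric].to_numpy(dtype=float)
            finite = vals[np.isfinite(vals)]
            mean = float(finite.mean()) if finite.size else np.nan
            sd = float(finite.std(ddof=1)) if finite.size > 1 else np.nan
            if finite.size > 1:
                half = _t_dist.ppf(0.975, finite.size - 1) * sd / np.sqrt(
                    finite.size
                )
            else:
                half = np.nan
            summaries.append(
                {
                    "condition": cond,
                    "metric": metric,
                    "n": int(vals.size),
                    "mean": mean,
                    "sd": sd,
                    "ci95_low": mean - half,
                    "ci95_high": mean + half,
                }
            )
    return per_image, pd.DataFrame(summaries)


def _degrade_set(
    hr_set: dict[str, np.ndarray], params: DegradationParams
) -> dict[str, np.ndarray]:
    out = {}
    for i, (image_id, hr) in enumerate(sorted(hr_set.items())):
        p = dataclasses.replace(params, seed=params.seed + i)
        out[image_id] = degrade(hr, p).lr_image
    return out


def run_sweep(
    grid: SweepGrid,
    train_set: dict[str, np.ndarray],
    test_set: dict[str, np.ndarray],
    train_cfg: _srcnn.TrainConfig | None = None,
    val_fraction: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Sweep each degradation parameter one-at-a-time from the baseline.

    For every grid point: simulate the LR sets, optionally train an SRCNN on
    the (LR, HR) training pairs (``train_cfg=None`` evaluates LR only), and
    record mean/SD PSNR and SSIM per condition.  Grid points violating
    m <= s are skipped and flagged in the returned table.
    """
    base = grid.fixed_baseline
    points: list[tuple[str, float, DegradationParams | None]] = []
    for d in grid.offsets_um:
        points.append(("offset_um", d,
                       _maybe_params(base, d_um=float(d))))
    for s in grid.inter_fiber_um:
        points.append(("inter_fiber_um", s,
                       _maybe_params(base, s_um=float(s))))
    for m in grid.diameters_um:
        points.append(("diameter_um", m,
                       _maybe_params(base, m_um=float(m))))

    rows = []
    for param_name, value, p in points:
        if p is None:
            rows.append(
                {
                    "parameter": param_name, "value": value,
                    "condition": "skipped", "reason": "m > s infeasible",
                }
            )
            continue
        lr_test = _degrade_set(test_set, p)
        sr_test = None
        if train_cfg is not None:
            lr_train = _degrade_set(train_set, p)
            ids = sorted(train_set)
            n_val = max(1, int(round(val_fraction * len(ids))))
            val_ids, tr_ids = ids[:n_val], ids[n_val:]
            model = _srcnn.build_model(seed=seed)
            _srcnn.train(
                model,
                [(lr_train[i], train_set[i]) for i in tr_ids],
                [(lr_train[i], train_set[i]) for i in val_ids],
                train_cfg,
            )
            sr_test = {
                i: _srcnn.super_resolve(model, lr_test[i]) for i in lr_test
            }
        _, summary = evaluate_conditions(test_set, lr_test, sr_test)
        # one row per (parameter, value, condition), metrics as columns
        for cond, grp in summary.groupby("condition"):
            row = {"parameter": param_name, "value": value,
                   "condition": cond, "reason": ""}
            for _, srow in grp.iterrows():
                row[f"{srow['metric']}_mean"] = srow["mean"]
                row[f"{srow['metric']}_sd"] = srow["sd"]
            rows.append(row)
    return pd.DataFrame(rows)


def _maybe_params(base: DegradationParams, **kw) -> DegradationParams | None:
    try:
        return dataclasses.replace(base, **kw)
    except ValueError:
        return None
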