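"""Three-layer super-resolution CNN (SRCNN) for LR microendoscopy images.

The network maps a reconstituted LR image (same grid as the HR image, so no
upsampling layer is needed) to a super-resolved estimate:

    conv 9x9, 64 -> leaky ReLU -> conv 1x1, 32 -> leaky ReLU -> conv 5x5, 1

with "same" zero padding throughout and no nonlinearity after the last
layer; for the default shapes this is 8,129 trainable parameters.  Training
minimizes pixelwise MSE against the HR target with Adam on randomly cropped
aligned patch pairs; the checkpoint with the best validation loss is kept.

The implementation is pure numpy: convolutions run through im2col + matmul
during training (patches are small) and through scipy.ndimage channel loops
for full-frame inference, where an im2col buffer would be needlessly large.
Given a seed, training is fully deterministic.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import correlate as _nd_correlate

__all__ = [
    "SRCNNConfig",
    "TrainConfig",
    "SRCNN",
    "build_model",
    "param_count",
    "extract_patches",
    "train",
    "super_resolve",
    "select_best_epoch",
]


@dataclass(frozen=True)
class SRCNNConfig:
    """Architecture hyperparameters."""

    kernel_sizes: tuple[int, int, int] = (9, 1, 5)
    channels: tuple[int, int, int] = (64, 32, 1)
    input_channels: int = 1
    leaky_slope: float = 0.2
    padding: str = "same"

    def __post_init__(self) -> None:
        if len(self.kernel_sizes) != len(self.channels):
            raise ValueError("kernel_sizes and channels must align")
        if any(k <= 0 for k in self.kernel_sizes):
            raise ValueError("kernel sizes must be positive")
        if any(c <= 0 for c in self.channels):
            raise ValueError("channel counts must be positive")
        if self.input_channels != 1:
            raise ValueError("only single-channel (grayscale) input supported")
        if self.padding != "same":
            raise ValueError("only 'same' padding is supported")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.

    The reference protocol is Adam at 1e-4, 300 epochs, batch 8, ten
    512x512 patches per image; reduced-scale runs shrink epochs/patches, not
    the architecture.
    """

    learning_rate: float = 1e-4
    epochs: int = 300
    batch_size: int = 8
    patches_per_image: int = 10
    patch_size_px: int = 512
    loss: str = "mse"
    optimizer: str = "adam"
    seed: int = 0
    checkpoint_rule: str = "best_validation_loss"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        for name in ("epochs", "batch_size", "patches_per_image",
                     "patch_size_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.loss != "mse":
            raise ValueError("only MSE loss is supported")
        if self.optimizer != "adam":
            raise ValueError("only Adam is supported")
        if self.checkpoint_rule != "best_validation_loss":
            raise ValueError("only best_validation_loss checkpointing")


def param_count(cfg: SRCNNConfig) -> int:
    """Trainable parameter count: sum of k*k*c_in*c_out + c_out per layer."""
    n = 0
    c_in = cfg.input_channels
    for k, c_out in zip(cfg.kernel_sizes, cfg.channels):
        n += k * k * c_in * c_out + c_out
        c_in = c_out
    return n


class SRCNN:
    """An SRCNN model: weights, config, and training history."""

    def __init__(self, cfg: SRCNNConfig, seed: int = 0) -> None:
        self.config = cfg
        self.history: dict[str, list[float]] = {"train_loss": [],
                                                "val_loss": []}
        self.best_epoch: int | None = None
        self.trained = False
        rng = np.random.default_rng(seed)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        c_in = cfg.input_channels
        for k, c_out in zip(cfg.kernel_sizes, cfg.channels):
            fan_in = k * k * c_in
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                           size=(k, k, c_in, c_out)).astype(np.float32)
            self.weights.append(w)
            self.biases.append(np.zeros(c_out, dtype=np.float32))
            c_in = c_out

    # ---- forward ---------------------------------------------------------

    def n_parameters(self) -> int:
        return int(sum(w.size for w in self.weights)
                   + sum(b.size for b in self.biases))

    def forward(self, image: np.ndarray) -> np.ndarray:
        """Forward pass on one 2-D image (unclipped raw output)."""
        image = np.asarray(image, dtype=np.float32)
        if image.ndim != 2:
            raise ValueError("expected a single 2-D grayscale image")
        x = image[..., None]
        slope = self.config.leaky_slope
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            x = _conv_same_nd(x, w, b)
            if i != last:
                x = np.where(x > 0, x, slope * x)
        return x[..., 0].astype(np.float64)

    def forward_batch(self, x: np.ndarray) -> np.ndarray:
        """Forward pass on a patch batch (N, H, W) via im2col."""
        acts, _ = _forward_cached(self, np.asarray(x, dtype=np.float32))
        return acts[-1][..., 0]

    def copy_weights(self) -> tuple[list[np.ndarray], list[np.ndarray]]:
        return ([w.copy() for w in self.weights],
                [b.copy() for b in self.biases])


def build_model(cfg: SRCNNConfig | None = None, seed: int = 0) -> SRCNN:
    """Instantiate an untrained SRCNN with He-normal weights, zero biases."""
    return SRCNN(cfg or SRCNNConfig(), seed=seed)


# ---- convolution primitives ---------------------------------------------


def _pad_same(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    return np.pad(
        x,
        ((0, 0), (kh // 2, kh - 1 - kh // 2),
         (kw // 2, kw - 1 - kw // 2), (0, 0)),
    )


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N, H, W, C) -> (N, H, W, kh, kw, C) sliding windows, zero padded."""
    xp = _pad_same(x, kh, kw)
    win = sliding_window_view(xp, (kh, kw), axis=(1, 2))  # N,H,W,C,kh,kw
    return np.ascontiguousarray(np.moveaxis(win, 3, 5))


def _conv_im2col(x: np.ndarray, w: np.ndarray, b: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Same-padded convolution; returns (output, cached columns)."""
    kh, kw, c_in, c_out = w.shape
    cols = _im2col(x, kh, kw)
    n, h, wd = x.shape[:3]
    out = cols.reshape(n * h * wd, kh * kw * c_in) @ w.reshape(-1, c_out)
    out = out.reshape(n, h, wd, c_out) + b
    return out.astype(np.float32), cols


def _conv_same_nd(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padded convolution of one (H, W, C_in) image via scipy loops.

    Memory-proportional to the image, not to image x kernel, so it scales to
    full 960x1280 frames.
    """
    kh, kw, c_in, c_out = w.shape
    h, wd = x.shape[:2]
    out = np.empty((h, wd, c_out), dtype=np.float32)
    if kh == kw == 1:
        np.dot(x, w[0, 0], out=out)
        out += b
        return out
    for j in range(c_out):
        acc = np.zeros((h, wd), dtype=np.float32)
        for i in range(c_in):
            acc += _nd_correlate(x[..., i], w[:, :, i, j],
                                 mode="constant", cval=0.0)
        out[..., j] = acc + b[j]
    return out


def _forward_cached(model: SRCNN, x: np.ndarray
                    ) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Batch forward keeping activations and im2col caches for backprop."""
    if x.ndim != 3:
        raise ValueError("expected a batch (N, H, W)")
    slope = model.config.leaky_slope
    a = x[..., None]
    acts = [a]
    caches = []
    last = len(model.weights) - 1
    for i, (w, b) in enumerate(zip(model.weights, model.biases)):
        z, cols = _conv_im2col(a, w, b)
        caches.append((cols, z))
        a = z if i == last else np.where(z > 0, z, slope * z)
        acts.append(a)
    return acts, caches


def _backward(model: SRCNN, acts, caches, d_out: np.ndarray
              ) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Gradients of the scalar loss w.r.t. every weight and bias."""
    slope = model.config.leaky_slope
    grads_w: list[np.ndarray] = [None] * len(model.weights)
    grads_b: list[np.ndarray] = [None] * len(model.weights)
    delta = d_out.astype(np.float32)
    for i in reversed(range(len(model.weights))):
        cols, z = caches[i]
        if i != len(model.weights) - 1:
            delta = delta * np.where(z > 0, 1.0, slope).astype(np.float32)
        kh, kw, c_in, c_out = model.weights[i].shape
        n, h, wd = delta.shape[:3]
        d_flat = delta.reshape(n * h * wd, c_out)
        grads_w[i] = (
            cols.reshape(n * h * wd, kh * kw * c_in).T @ d_flat
        ).reshape(model.weights[i].shape)
        grads_b[i] = d_flat.sum(axis=0)
        if i > 0:
            # propagate through the conv: same-padded correlation with the
            # spatially flipped, channel-transposed kernel (exact for odd k)
            w_flip = model.weights[i][::-1, ::-1].swapaxes(2, 3)
            delta, _ = _conv_im2col(
                delta, np.ascontiguousarray(w_flip),
                np.zeros(c_in, dtype=np.float32),
            )
    return grads_w, grads_b


# ---- data & training -----------------------------------------------------


def extract_patches(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    tc: TrainConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Aligned random LR/HR patch crops, ``patches_per_image`` per pair.

    Crop positions are uniform over valid top-left corners and identical
    between the LR and HR member of each pair; deterministic under
    ``tc.seed``.
    """
    rng = np.random.default_rng(tc.seed)
    ps = tc.patch_size_px
    lr_patches, hr_patches = [], []
    for lr, hr in pairs:
        lr = np.asarray(lr)
        hr = np.asarray(hr)
        if lr.shape != hr.shape:
            raise ValueError("LR/HR pair shapes differ")
        h, w = lr.shape
        if h < ps or w < ps:
            raise ValueError(
                f"image {lr.shape} smaller than patch size {ps}"
            )
        ys = rng.integers(0, h - ps + 1, size=tc.patches_per_image)
        xs = rng.integers(0, w - ps + 1, size=tc.patches_per_image)
        for y, x in zip(ys, xs):
            lr_patches.append(lr[y:y + ps, x:x + ps])
            hr_patches.append(hr[y:y + ps, x:x + ps])
    return (np.stack(lr_patches).astype(np.float32),
            np.stack(hr_patches).astype(np.float32))


def select_best_epoch(history: dict[str, list[float]]) -> int:
    """Index of the epoch with the minimum recorded validation loss."""
    val = history["val_loss"]
    if not val:
        raise ValueError("history has no validation losses")
    return int(np.argmin(val))


def _mse_batched(model: SRCNN, x: np.ndarray, y: np.ndarray,
                 batch: int) -> float:
    total, n = 0.0, 0
    for i in range(0, len(x), batch):
        pred = model.forward_batch(x[i:i + batch])
        diff = pred - y[i:i + batch]
        total += float(np.sum(diff.astype(np.float64) ** 2))
        n += diff.size
    return total / n


def train(
    model: SRCNN,
    train_pairs: list[tuple[np.ndarray, np.ndarray]],
    val_pairs: list[tuple[np.ndarray, np.ndarray]],
    tc: TrainConfig,
) -> SRCNN:
    """Train with Adam on MSE; keep the best-validation-loss weights.

    Patches are extracted once up front; each epoch reshuffles them.  The
    returned model's weights are those of ``best_epoch``; the full per-epoch
    train/val loss history is recorded on the model.
    """
    if not train_pairs or not val_pairs:
        raise ValueError("train and validation sets must be nonempty")
    x_tr, y_tr = extract_patches(train_pairs, tc)
    # distinct stream for validation crop positions
    x_va, y_va = extract_patches(
        val_pairs, dataclasses.replace(tc, seed=tc.seed + 1)
    )

    rng = np.random.default_rng(tc.seed)
    m_w = [np.zeros_like(w) for w in model.weights]
    v_w = [np.zeros_like(w) for w in model.weights]
    m_b = [np.zeros_like(b) for b in model.biases]
    v_b = [np.zeros_like(b) for b in model.biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    best_val = np.inf
    best_weights = model.copy_weights()
    model.history = {"train_loss": [], "val_loss": []}

    for epoch in range(tc.epochs):
        order = rng.permutation(len(x_tr))
        epoch_loss, n_seen = 0.0, 0
        for i in range(0, len(order), tc.batch_size):
            idx = order[i:i + tc.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            acts, caches = _forward_cached(model, xb)
            pred = acts[-1][..., 0]
            diff = pred - yb
            loss = float(np.mean(diff.astype(np.float64) ** 2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged to non-finite loss at epoch {epoch}"
                )
            epoch_loss += loss * diff.size
            n_seen += diff.size
            d_out = (2.0 * diff / diff.size)[..., None]
            g_w, g_b = _backward(model, acts, caches, d_out)
            step += 1
            corr1 = 1.0 - beta1**step
            corr2 = 1.0 - beta2**step
            for j in range(len(model.weights)):
                for param, grad, m_, v_ in (
                    (model.weights[j], g_w[j], m_w[j], v_w[j]),
                    (model.biases[j], g_b[j], m_b[j], v_b[j]),
                ):
                    m_ *= beta1
                    m_ += (1 - beta1) * grad
                    v_ *= beta2
                    v_ += (1 - beta2) * grad**2
                    param -= (
                        tc.learning_rate * (m_ / corr1)
                        / (np.sqrt(v_ / corr2) + eps)
                    ).astype(param.dtype)
        val_loss = _mse_batched(model, x_va, y_va, tc.batch_size)
        model.history["train_loss"].append(epoch_loss / n_seen)
        model.history["val_loss"].append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_weights = model.copy_weights()

    model.weights, model.biases = best_weights
    model.best_epoch = select_best_epoch(model.history)
    model.trained = True
    return model


def super_resolve(model: SRCNN, lr: np.ndarray) -> np.ndarray:
    """Super-resolve a full LR frame in a single forward pass, clipped to
    [0, 1]."""
    if not model.trained:
        raise ValueError("model has not been trained")
    out = model.forward(lr)
    return np.clip(out, 0.0, 1.0)
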