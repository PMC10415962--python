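"""Loss functions and the shared mini-batch training loop.

Segmentation uses an equally weighted soft-Dice + binary cross-entropy loss on
the logit map; slice regression uses mean squared error on the (scaled) offset.
Gradients are returned with respect to the network logits so the model classes
stay loss-agnostic.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .layers import F32, Adam, sigmoid


class TrainingDivergence(RuntimeError):
    """Raised when the loss becomes non-finite; carries the offending epoch."""

    def __init__(self, epoch: int):
        super().__init__(f"training loss became non-finite at epoch {epoch}")
        self.epoch = epoch


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over the batch; grad wrt pred."""
    diff = pred - target.astype(F32)
    loss = float(np.mean(diff ** 2))
    return loss, (2.0 / diff.size) * diff


def dice_bce_loss(logits: np.ndarray, target: np.ndarray,
                  smooth: float = 1.0) -> tuple[float, np.ndarray]:
    """Soft-Dice + BCE (equal weights) on (N, 1, H, W) logits; grad wrt logits."""
    t = target.astype(F32)
    p = sigmoid(logits)
    n = logits.shape[0]
    npix = logits[0].size

    # BCE on logits: log(1+e^z) - t*z, numerically stable
    z = logits
    bce = float(np.mean(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))))
    g_bce = (p - t) / (n * npix)

    axes = (1, 2, 3)
    inter = (p * t).sum(axis=axes)
    denom = p.sum(axis=axes) + t.sum(axis=axes)
    dice = (2 * inter + smooth) / (denom + smooth)
    dice_loss = float(np.mean(1 - dice))
    # d(dice)/dp = (2t*(denom+s) - (2*inter+s)) / (denom+s)^2
    num = 2 * t * (denom + smooth)[:, None, None, None] - (2 * inter + smooth)[:, None, None, None]
    g_dice_p = -num / ((denom + smooth) ** 2)[:, None, None, None] / n
    g_dice = g_dice_p * p * (1 - p)

    return bce + dice_loss, (g_bce + g_dice).astype(F32)


def augment_pair(image: np.ndarray, mask: np.ndarray | None,
                 max_shift_px: float, max_rot_deg: float,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray | None]:
    """Random small translation/rotation; masks use nearest-neighbour resampling."""
    dy, dx = rng.uniform(-max_shift_px, max_shift_px, size=2)
    ang = rng.uniform(-max_rot_deg, max_rot_deg)
    img = ndimage.shift(image, (dy, dx), order=1, mode="constant", cval=0.0)
    if abs(ang) > 1e-9:
        img = ndimage.rotate(img, ang, reshape=False, order=1, mode="constant", cval=0.0)
    out_mask = None
    if mask is not None:
        m = ndimage.shift(mask.astype(F32), (dy, dx), order=0, mode="constant", cval=0.0)
        if abs(ang) > 1e-9:
            m = ndimage.rotate(m, ang, reshape=False, order=0, mode="constant", cval=0.0)
        out_mask = m >= 0.5
    return img.astype(F32), out_mask


def run_epochs(model, inputs: np.ndarray, targets: np.ndarray, *,
               loss_fn, epochs: int, lr: float, batch_size: int,
               rng: np.random.Generator,
               augment=None, cosine_decay: bool = True) -> list[float]:
    """Shuffled mini-batch Adam training; returns per-epoch mean loss.

    ``augment`` is an optional callable (image, target, rng) -> (image, target)
    applied per sample each epoch. The learning rate follows a cosine decay
    from ``lr`` to ``lr/10`` over the epochs unless ``cosine_decay`` is False.
    """
    opt = Adam(model.params(), lr=lr)
    n = inputs.shape[0]
    history: list[float] = []
    for epoch in range(epochs):
        if cosine_decay and epochs > 1:
            frac = epoch / (epochs - 1)
            opt.lr = 0.1 * lr + 0.45 * lr * (1 + np.cos(np.pi * frac))
        order = rng.permutation(n)
        total, seen = 0.0, 0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb = inputs[idx]
            yb = targets[idx]
            if augment is not None:
                xb = xb.copy()
                yb = yb.copy()
                for j in range(len(idx)):
                    xb[j], yb[j] = augment(xb[j], yb[j], rng)
            opt.zero_grad()
            logits = model.forward(xb[:, None], training=True)
            if yb.ndim == 1:
                loss, grad = loss_fn(logits[:, 0], yb)
                model.backward(grad[:, None].astype(F32))
            else:
                loss, grad = loss_fn(logits, yb[:, None])
                model.backward(grad)
            if not np.isfinite(loss):
                raise TrainingDivergence(epoch + 1)
            opt.step()
            total += loss * len(idx)
            seen += len(idx)
        history.append(total / seen)
    return history
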