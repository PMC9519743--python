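"""Composite GAN losses with an analytically differentiated SSIM term.

The generator objective combines three terms weighted by ``lambda``, ``nu``
and the remainder ``1 - lambda - nu``:

    L_G = lambda * (-log D(G(x)))
        + nu * (1/N) * sum |y - G(x)|
        + (1 - lambda - nu) * (1 - SSIM(y, G(x)))

and the discriminator minimizes the negated two-player value

    L_D = -[log D(y) + log(1 - D(G(x)))].

Patch-map discriminator scores are reduced by their mean before the log.
SSIM here uses an 11x11 Gaussian window (sigma 1.5) applied with zero
padding, which makes the windowing operator self-adjoint so that the
gradient with respect to the prediction is exact; the metrics module's SSIM
(valid-window convention) agrees away from image borders.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate1d

__all__ = ["LossWeights", "generator_loss", "discriminator_loss", "ssim_with_grad"]

log = logging.getLogger(__name__)

_EPS = 1e-7


@dataclass(frozen=True)
class LossWeights:
    """Eq-style weights: adversarial ``lam``, MAE ``nu``, SSIM remainder."""

    lam: float = 0.05
    nu: float = 0.60

    def __post_init__(self) -> None:
        if self.lam < 0 or self.nu < 0:
            raise ValueError("loss weights must be non-negative")
        if self.lam + self.nu > 1.0 + 1e-12:
            raise ValueError("lambda + nu must not exceed 1 (SSIM weight 1-lambda-nu)")

    @property
    def ssim_weight(self) -> float:
        return 1.0 - self.lam - self.nu


def _gaussian_kernel(size: int = 11, sigma: float = 1.5) -> np.ndarray:
    x = np.arange(size) - (size - 1) / 2.0
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return (k / k.sum()).astype(np.float64)


_WIN = _gaussian_kernel()


def _blur(x: np.ndarray) -> np.ndarray:
    """Separable Gaussian windowing with zero padding (self-adjoint)."""
    y = correlate1d(x, _WIN, axis=-1, mode="constant", cval=0.0)
    return correlate1d(y, _WIN, axis=-2, mode="constant", cval=0.0)


def ssim_with_grad(pred: np.ndarray, target: np.ndarray, data_range: float = 1.0):
    """Mean SSIM between prediction and target plus d(SSIM)/d(pred).

    Works on 2D images or batched (B, 1, H, W) maps; the mean is over all
    pixels (and batch). The gradient is exact for the zero-padded windowing
    used here, which is what the training loop differentiates through.
    """
    if pred.shape != target.shape:
        raise ValueError("shape mismatch")
    x = pred.astype(np.float64)
    y = target.astype(np.float64)
    C1 = (0.01 * data_range) ** 2
    C2 = (0.03 * data_range) ** 2
    mx, my = _blur(x), _blur(y)
    sxx, syy, sxy = _blur(x * x), _blur(y * y), _blur(x * y)
    A1 = 2 * mx * my + C1
    A2 = 2 * (sxy - mx * my) + C2
    B1 = mx**2 + my**2 + C1
    B2 = (sxx - mx**2) + (syy - my**2) + C2
    S = (A1 * A2) / (B1 * B2)
    n = S.size
    # partials of mean(S) w.r.t. the blurred statistics, then adjoint blur
    dS_dmx = (2 * my * (A2 - A1)) / (B1 * B2) - 2 * mx * S * (1 / B1 - 1 / B2)
    dS_dsxx = -S / B2
    dS_dsxy = 2 * A1 / (B1 * B2)
    grad = (_blur(dS_dmx) + 2 * x * _blur(dS_dsxx) + y * _blur(dS_dsxy)) / n
    return float(S.mean()), grad.astype(np.float32)


def generator_loss(
    d_fake: np.ndarray,
    pred: np.ndarray,
    target: np.ndarray,
    weights: LossWeights = LossWeights(),
    return_grads: bool = False,
):
    """Composite generator loss; optionally its gradients.

    With ``return_grads=True`` returns ``(loss, g_pred, g_dfake)`` where
    ``g_pred`` is the gradient of the MAE and SSIM terms with respect to the
    prediction and ``g_dfake`` the gradient of the adversarial term with
    respect to the discriminator's patch scores (to be chained through the
    discriminator back to the prediction by the caller).
    """
    if pred.shape != target.shape:
        raise ValueError("prediction/target shape mismatch")
    d_fake = np.asarray(d_fake, dtype=np.float64)
    mean_fake = float(d_fake.mean())
    if mean_fake < _EPS:
        log.warning("discriminator score clamped at %g", _EPS)
        mean_fake = _EPS
    n = pred.size
    diff = pred.astype(np.float64) - target.astype(np.float64)
    mae = float(np.abs(diff).mean())
    ssim_val, ssim_grad = ssim_with_grad(pred, target)
    loss = (
        weights.lam * (-np.log(mean_fake))
        + weights.nu * mae
        + weights.ssim_weight * (1.0 - ssim_val)
    )
    if not return_grads:
        return float(loss)
    g_pred = (
        weights.nu * np.sign(diff) / n - weights.ssim_weight * ssim_grad
    ).astype(np.float32)
    g_dfake = np.full(
        d_fake.shape, -weights.lam / (mean_fake * d_fake.size), dtype=np.float32
    )
    return float(loss), g_pred, g_dfake


def discriminator_loss(
    d_real: np.ndarray, d_fake: np.ndarray, return_grads: bool = False
):
    """Negated two-player objective for the discriminator.

    Patch scores are mean-reduced; boundary scores are clamped at 1e-7.
    """
    d_real = np.asarray(d_real, dtype=np.float64)
    d_fake = np.asarray(d_fake, dtype=np.float64)
    mr = float(np.clip(d_real.mean(), _EPS, 1 - _EPS))
    mf = float(np.clip(d_fake.mean(), _EPS, 1 - _EPS))
    loss = -(np.log(mr) + np.log(1.0 - mf))
    if not return_grads:
        return float(loss)
    g_real = np.full(d_real.shape, -1.0 / (mr * d_real.size), dtype=np.float32)
    g_fake = np.full(d_fake.shape, 1.0 / ((1.0 - mf) * d_fake.size), dtype=np.float32)
    return float(loss), g_real, g_fake
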