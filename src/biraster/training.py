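"""Adversarial training of the correction network, with SSIM checkpointing.

Generator and discriminator are updated alternately (one discriminator step
then one generator step per batch). After every epoch the mean SSIM over
the validation split is computed and the best-so-far generator weights are
retained as the checkpoint — training is allowed to run its full budget but
the returned model is the validation optimum. All randomness (shuffling)
derives from the training seed, so runs are reproducible on CPU up to
floating-point reduction order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .losses import LossWeights, discriminator_loss, generator_loss
from .metrics import ssim
from .model import (
    Discriminator,
    DiscriminatorConfig,
    Generator,
    GeneratorConfig,
)
from .nn import Adam

__all__ = [
    "TrainConfig",
    "TrainResult",
    "train",
    "infer",
    "save_checkpoint",
    "load_checkpoint",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters.

    Adam with moments (0.5, 0.999) and a small L2 weight decay is the
    stable default for pix2pix-style adversarial image translation; the
    epoch cap defaults to 200 with the validation-SSIM checkpoint deciding
    which epoch's weights survive.
    """

    epochs_max: int = 200
    batch_size: int = 8
    lr_g: float = 2e-4
    lr_d: float = 2e-4
    betas: tuple = (0.5, 0.999)
    weight_decay: float = 1e-5
    loss_weights: LossWeights = field(default_factory=LossWeights)
    max_grad_norm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs_max < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch size must be positive")
        if min(self.lr_g, self.lr_d) <= 0:
            raise ValueError("learning rates must be positive")


@dataclass
class TrainResult:
    generator: Generator
    best_epoch: int
    best_val_ssim: float
    log: list  # per-epoch dicts: epoch, g_loss, d_loss, val_ssim

    def log_frame(self):
        import pandas as pd

        return pd.DataFrame(self.log)


def _clip_grads(module, max_norm: float) -> None:
    """Global-norm gradient clipping; tames the unbounded adversarial term."""
    if not max_norm or max_norm <= 0:
        return
    total = np.sqrt(sum(float((p.grad**2).sum()) for p in module.params()))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in module.params():
            p.grad *= scale


def _stack(dataset, idx):
    x = np.stack([np.asarray(dataset[i].input_img, np.float32) for i in idx])[:, None]
    y = np.stack([np.asarray(dataset[i].target_img, np.float32) for i in idx])[:, None]
    return x, y


def _val_ssim(generator, x_val, y_val, batch: int) -> float:
    vals = []
    for i in range(0, len(x_val), batch):
        pred = generator.forward(x_val[i : i + batch], train=False)
        for p, t in zip(pred[:, 0], y_val[i : i + batch, 0]):
            vals.append(ssim(p, t))
    return float(np.mean(vals))


def train(
    generator: Generator,
    discriminator: Discriminator,
    dataset,
    split,
    config: TrainConfig = TrainConfig(),
) -> TrainResult:
    """Alternating GAN training with best-validation-SSIM checkpointing.

    ``dataset`` is a sequence of :class:`~biraster.core.PairedSample`;
    ``split`` a :class:`~biraster.core.SplitIndices`. Raises on empty train
    or validation splits and aborts with a diagnostic if a loss goes
    non-finite.
    """
    if len(split.train) == 0 or len(split.validation) == 0:
        raise ValueError("train and validation splits must be non-empty")
    rng = np.random.default_rng(config.seed)
    x_tr, y_tr = _stack(dataset, split.train)
    x_val, y_val = _stack(dataset, split.validation)
    opt_g = Adam(generator.params(), config.lr_g, config.betas, weight_decay=config.weight_decay)
    opt_d = Adam(discriminator.params(), config.lr_d, config.betas, weight_decay=config.weight_decay)
    w = config.loss_weights
    best_ssim, best_epoch, best_state = -np.inf, 0, None
    history = []
    n = len(x_tr)
    for epoch in range(1, config.epochs_max + 1):
        perm = rng.permutation(n)
        g_losses, d_losses = [], []
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            x, y = x_tr[idx], y_tr[idx]
            pred = generator.forward(x)
            # --- discriminator step (generator output detached) ---
            discriminator.zero_grad()
            d_real = discriminator.forward(y)
            mr = float(np.clip(d_real.mean(), 1e-7, 1 - 1e-7))
            discriminator.backward(
                np.full(d_real.shape, -1.0 / (mr * d_real.size), np.float32)
            )
            d_fake = discriminator.forward(pred)
            mf = float(np.clip(d_fake.mean(), 1e-7, 1 - 1e-7))
            discriminator.backward(
                np.full(d_fake.shape, 1.0 / ((1.0 - mf) * d_fake.size), np.float32)
            )
            d_loss = discriminator_loss(d_real, d_fake)
            _clip_grads(discriminator, config.max_grad_norm)
            opt_d.step()
            # --- generator step (adversarial grad through updated D) ---
            generator.zero_grad()
            discriminator.zero_grad()
            pred = generator.forward(x)
            d_fake2 = discriminator.forward(pred)
            g_loss, g_pred, g_dfake = generator_loss(
                d_fake2, pred, y, w, return_grads=True
            )
            g_from_d = discriminator.backward(g_dfake)
            discriminator.zero_grad()  # D params are not updated on G's turn
            generator.backward(g_pred + g_from_d)
            _clip_grads(generator, config.max_grad_norm)
            opt_g.step()
            if not (np.isfinite(g_loss) and np.isfinite(d_loss)):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} (g={g_loss}, d={d_loss})"
                )
            g_losses.append(g_loss)
            d_losses.append(d_loss)
        val = _val_ssim(generator, x_val, y_val, config.batch_size)
        history.append(
            {
                "epoch": epoch,
                "g_loss": float(np.mean(g_losses)),
                "d_loss": float(np.mean(d_losses)),
                "val_ssim": val,
            }
        )
        log.info("epoch %d g=%.4f d=%.4f val_ssim=%.4f", epoch, history[-1]["g_loss"], history[-1]["d_loss"], val)
        if val > best_ssim:
            best_ssim, best_epoch = val, epoch
            best_state = [p.copy() for p in generator.state_arrays()]
    generator.load_state_arrays(best_state)
    return TrainResult(generator, best_epoch, best_ssim, history)


def infer(generator: Generator, image: np.ndarray) -> np.ndarray:
    """Correct one image (2D) or a batch (K, H, W) with a trained generator.

    Inputs whose sides are not multiples of ``2**n_scales`` are reflect-
    padded transparently and the output is cropped back.
    """
    arr = np.asarray(image, dtype=np.float32)
    single = arr.ndim == 2
    if single:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError("expected a 2D image or a (K, H, W) batch")
    k, h, wdt = arr.shape
    mult = 2 ** generator.config.n_scales
    ph = (-h) % mult
    pw = (-wdt) % mult
    if ph or pw:
        arr = np.pad(arr, ((0, 0), (0, ph), (0, pw)), mode="reflect")
    out = generator.forward(arr[:, None], train=False)[:, 0, :h, :wdt]
    return out[0] if single else out


def save_checkpoint(path, generator: Generator, meta: dict | None = None) -> None:
    """Serialize generator weights with the architecture config embedded."""
    arrays = {f"param_{i}": a for i, a in enumerate(generator.state_arrays())}
    header = {"generator_config": generator.config.to_dict(), "meta": meta or {}}
    np.savez(path, __header__=np.frombuffer(json.dumps(header).encode(), np.uint8), **arrays)


def load_checkpoint(path) -> Generator:
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        cfg = GeneratorConfig(**header["generator_config"])
        gen = Generator(cfg)
        arrays = [data[f"param_{i}"] for i in range(len(data.files) - 1)]
    gen.load_state_arrays(arrays)
    return gen
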