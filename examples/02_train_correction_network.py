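"""Train a scaled-down correction network and measure the improvement.

Uses small 64x64 crops and a narrow generator so the run finishes in a few
minutes on a laptop CPU; the same code scales to the full 192x192 /
7.6M-parameter configuration by swapping the configs.
"""

import numpy as np

from biraster.losses import LossWeights
from biraster.metrics import bad, ssim
from biraster.model import (
    DiscriminatorConfig,
    GeneratorConfig,
    build_discriminator,
    build_generator,
)
from biraster.preprocess import split_dataset
from biraster.simulate import generate_paired_dataset
from biraster.training import TrainConfig, infer, train

pairs, _ = generate_paired_dataset(
    120, seed=11, crop_size=64, crops_per_scene=4, ref_pixel_um=2.0
)
split = split_dataset(len(pairs), 0.2, 0.1, seed=5)

gen = build_generator(
    GeneratorConfig(n_scales=3, dense_layers_per_block=2, growth_rate=4,
                    base_channels=8, ms_channels=4, seed=1)
)
disc = build_discriminator(DiscriminatorConfig(channels=(8, 16, 32, 64), seed=1))
cfg = TrainConfig(
    epochs_max=20, batch_size=4, lr_g=8e-4, lr_d=2e-4, seed=0,
    loss_weights=LossWeights(0.05, 0.60),
)

result = train(gen, disc, pairs, split, cfg)
print(f"best epoch {result.best_epoch}, validation SSIM {result.best_val_ssim:.4f}")

test = [pairs[i] for i in split.test]
outs = [infer(result.generator, p.input_img) for p in test]
print(f"held-out SSIM  input {np.mean([ssim(p.input_img, p.target_img) for p in test]):.4f}"
      f" -> corrected {np.mean([ssim(o, p.target_img) for o, p in zip(outs, test)]):.4f}")
print(f"held-out BAD   input {np.mean([bad(p.input_img, p.target_img) for p in test]):.4f}"
      f" -> corrected {np.mean([bad(o, p.target_img) for o, p in zip(outs, test)]):.4f}")
# higher SSIM / lower BAD for the corrected column = the network aligned
# the backward sweeps rather than merely smoothing them.
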