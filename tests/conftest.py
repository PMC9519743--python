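"""Shared fixtures.

The two expensive fixtures train real networks and are session-scoped:
``trained_corrector`` performs the scaled-down end-to-end study (200 paired
64x64 crops, 3-scale generator at base width 8, 25 epochs) used by the
correction-quality tests, and ``identity_generator`` trains briefly on
aligned (zero-jitter) pairs so the network's identity calibration can be
probed. Everything else is cheap and function-scoped.
"""

from __future__ import annotations

import numpy as np
import pytest

from biraster.core import JitterModel, ScanGeometry
from biraster.losses import LossWeights
from biraster.model import (
    DiscriminatorConfig,
    GeneratorConfig,
    build_discriminator,
    build_generator,
)
from biraster.preprocess import split_dataset
from biraster.simulate import generate_paired_dataset
from biraster.training import TrainConfig, train

# scaled-down study conditions shared by training-dependent tests
SCALED_GEN = GeneratorConfig(
    n_scales=3, dense_layers_per_block=2, growth_rate=4, base_channels=8, ms_channels=4, seed=1
)
SCALED_DISC = DiscriminatorConfig(channels=(8, 16, 32, 64), seed=1)
SCALED_TRAIN = TrainConfig(
    epochs_max=25,
    batch_size=4,
    lr_g=8e-4,
    lr_d=2e-4,
    seed=0,
    loss_weights=LossWeights(0.05, 0.60),
)


@pytest.fixture(scope="session")
def scaled_dataset():
    """200 paired 64x64 crops with the default jitter model (fixed seed)."""
    pairs, manifest = generate_paired_dataset(
        200, seed=1001, crop_size=64, crops_per_scene=4, ref_pixel_um=2.0
    )
    return pairs, manifest


@pytest.fixture(scope="session")
def scaled_split(scaled_dataset):
    pairs, _ = scaled_dataset
    return split_dataset(len(pairs), 0.2, 0.1, seed=5)


@pytest.fixture(scope="session")
def trained_corrector(scaled_dataset, scaled_split):
    """Train the scaled correction network once per session."""
    pairs, _ = scaled_dataset
    gen = build_generator(SCALED_GEN)
    disc = build_discriminator(SCALED_DISC)
    return train(gen, disc, pairs, scaled_split, SCALED_TRAIN)


@pytest.fixture(scope="session")
def identity_dataset():
    """Aligned (zero-jitter, noiseless) pairs: input equals target."""
    pairs, _ = generate_paired_dataset(
        48,
        jitter=JitterModel.zero(),
        seed=2002,
        crop_size=64,
        crops_per_scene=4,
        noise_sigma=0.0,
        ref_pixel_um=2.0,
    )
    return pairs


@pytest.fixture(scope="session")
def identity_generator(identity_dataset):
    """Generator trained to reproduce its input (identity calibration)."""
    split = split_dataset(len(identity_dataset), 0.2, 0.1, seed=3)
    gen = build_generator(SCALED_GEN)
    disc = build_discriminator(SCALED_DISC)
    cfg = TrainConfig(
        epochs_max=14,
        batch_size=4,
        lr_g=8e-4,
        lr_d=2e-4,
        seed=0,
        loss_weights=LossWeights(0.0, 0.65),
    )
    result = train(gen, disc, identity_dataset, split, cfg)
    return result.generator, identity_dataset, split


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def small_geometry():
    """A small scan geometry for fast trajectory/acquisition tests."""
    return ScanGeometry(fov_x_mm=0.4, fov_y_mm=0.4, n_fast=100, y_step_um=4.0)
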