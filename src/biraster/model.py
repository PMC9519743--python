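"""MS-FD-U-Net generator and patch discriminator.

The generator is a fully-dense U-Net with four departures from the plain
variant, mirroring the correction network this package implements:

1. **Multiscale input branches** — the raw input is median-pooled by
   ``2**s``, passed through a 1x1 convolution to adjust channels, and
   concatenated into the decoder block at scale ``s``, exposing the
   misalignment pattern to every decoding stage directly.
2. **Strided-convolution downsampling** — each encoder stage ends in a
   3x3 convolution with stride two (a learned pooling).
3. **Pixel-shuffle upsampling** — decoder stages upsample by sub-pixel
   rearrangement instead of transposed convolution, which removes the
   transposed convolution's checkerboard fingerprint.
4. **Three resolution scales** rather than four.

Dense blocks follow the DenseNet pattern: every convolution inside a block
receives the concatenation of the block input and all previous layer
outputs, with a per-scale growth rate that doubles at each downsampling.
The discriminator is five 3x3 convolutions in sequence (LReLU between,
sigmoid after the last) producing a patch map of real/fake scores.

Reference configurations are calibrated so that the generator holds
~7.6 million and the discriminator ~1.6 million trainable parameters
(see ``scripts/calibrate_model.py``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Conv2d, LeakyReLU, Module, PixelShuffle, Sigmoid, median_pool

__all__ = [
    "GeneratorConfig",
    "DiscriminatorConfig",
    "REFERENCE_GENERATOR",
    "REFERENCE_DISCRIMINATOR",
    "DenseBlock",
    "Generator",
    "Discriminator",
    "build_generator",
    "build_discriminator",
    "count_parameters",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Architecture hyperparameters of the generator.

    ``base_channels`` sets the channel width at full resolution; widths and
    dense growth rates double at each coarser scale. ``ms_channels`` is the
    width of each multiscale input branch after its 1x1 convolution.
    """

    n_scales: int = 3
    dense_layers_per_block: int = 4
    growth_rate: int = 17
    base_channels: int = 36
    ms_channels: int = 16
    lrelu_slope: float = 0.2
    in_channels: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_scales < 1:
            raise ValueError("need at least one scale")
        if min(self.dense_layers_per_block, self.growth_rate, self.base_channels) < 1:
            raise ValueError("block depth, growth rate and width must be positive")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class DiscriminatorConfig:
    """Five sequential convolutions; widths calibrated to the parameter budget."""

    channels: tuple = (65, 130, 260, 520)
    strides: tuple = (2, 2, 2, 1, 1)
    lrelu_slope: float = 0.2
    in_channels: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.channels) != 4 or len(self.strides) != 5:
            raise ValueError("discriminator has exactly five convolutional layers")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


class DenseBlock(Module):
    """Fully-dense convolution block: layer i sees all previous outputs."""

    def __init__(self, cin, n_layers, growth, slope, rng):
        self.cin = cin
        self.growth = growth
        self.convs = [
            Conv2d(cin + i * growth, growth, 3, rng=rng) for i in range(n_layers)
        ]
        self.acts = [LeakyReLU(slope) for _ in range(n_layers)]
        self.cout = cin + n_layers * growth

    def forward(self, x, train: bool = True):
        feats = [x]
        for conv, act in zip(self.convs, self.acts):
            h = np.concatenate(feats, axis=1)
            feats.append(act.forward(conv.forward(h, train), train))
        return np.concatenate(feats, axis=1)

    def backward(self, gy):
        g = self.growth
        c0 = self.cin
        gx0 = gy[:, :c0].copy()
        gys = [gy[:, c0 + i * g : c0 + (i + 1) * g].copy() for i in range(len(self.convs))]
        for i in range(len(self.convs) - 1, -1, -1):
            gcat = self.convs[i].backward(self.acts[i].backward(gys[i]))
            gx0 += gcat[:, :c0]
            for j in range(i):
                gys[j] += gcat[:, c0 + j * g : c0 + (j + 1) * g]
        return gx0


class Generator(Module):
    """Multiscale fully-dense U-Net mapping a misaligned image to [0, 1]."""

    def __init__(self, config: GeneratorConfig):
        rng = np.random.default_rng(config.seed)
        self.config = config
        S, L = config.n_scales, config.dense_layers_per_block
        b, g, m = config.base_channels, config.growth_rate, config.ms_channels
        sl = config.lrelu_slope
        ch = [b * 2**s for s in range(S + 1)]
        gr = [g * 2**s for s in range(S + 1)]

        self.stem = Conv2d(config.in_channels, ch[0], 3, rng=rng)
        self.stem_act = LeakyReLU(sl)
        self.enc_blocks, self.downs, self.down_acts = [], [], []
        for s in range(S):
            blk = DenseBlock(ch[s], L, gr[s], sl, rng)
            self.enc_blocks.append(blk)
            self.downs.append(Conv2d(blk.cout, ch[s + 1], 3, stride=2, rng=rng))
            self.down_acts.append(LeakyReLU(sl))
        self.bottleneck = DenseBlock(ch[S], L, gr[S], sl, rng)

        self.up_convs, self.up_acts, self.shuffles = [], [], []
        self.ms_convs, self.ms_acts, self.dec_blocks = [], [], []
        cur = self.bottleneck.cout
        for s in range(S - 1, -1, -1):
            self.up_convs.append(Conv2d(cur, 4 * ch[s], 1, rng=rng))
            self.up_acts.append(LeakyReLU(sl))
            self.shuffles.append(PixelShuffle(2))
            self.ms_convs.append(Conv2d(config.in_channels, m, 1, rng=rng))
            self.ms_acts.append(LeakyReLU(sl))
            cat = ch[s] + self.enc_blocks[s].cout + m
            blk = DenseBlock(cat, L, gr[s], sl, rng)
            self.dec_blocks.append(blk)
            cur = blk.cout
        self.head = Conv2d(cur, 1, 1, rng=rng)
        self.out_act = Sigmoid()

    # -- forward ---------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        S = self.config.n_scales
        if x.ndim != 4:
            raise ValueError("expected (batch, channel, height, width) input")
        if x.shape[2] % 2**S or x.shape[3] % 2**S:
            raise ValueError(f"input sides must be multiples of {2**S}")
        h = self.stem_act.forward(self.stem.forward(x, train), train)
        skips = []
        for s in range(S):
            h = self.enc_blocks[s].forward(h, train)
            skips.append(h)
            h = self.down_acts[s].forward(self.downs[s].forward(h, train), train)
        h = self.bottleneck.forward(h, train)
        self._cat_specs = []
        for i, s in enumerate(range(S - 1, -1, -1)):
            h = self.up_acts[i].forward(self.up_convs[i].forward(h, train), train)
            h = self.shuffles[i].forward(h, train)
            ms_in = median_pool(x, 2**s)
            ms = self.ms_acts[i].forward(self.ms_convs[i].forward(ms_in, train), train)
            parts = [h, skips[s], ms]
            self._cat_specs.append([p.shape[1] for p in parts])
            h = np.concatenate(parts, axis=1)
            h = self.dec_blocks[i].forward(h, train)
        return self.out_act.forward(self.head.forward(h, train), train)

    # -- backward --------------------------------------------------------
    def backward(self, gy: np.ndarray) -> None:
        """Accumulate parameter gradients for an upstream output gradient.

        The gradient with respect to the raw input is not propagated into
        the median-pooled multiscale branches (the input is a leaf).
        """
        S = self.config.n_scales
        g = self.head.backward(self.out_act.backward(gy))
        gskips = [None] * S
        for i in range(S - 1, -1, -1):
            s = S - 1 - i
            g = self.dec_blocks[i].backward(g)
            c_up, c_skip, c_ms = self._cat_specs[i]
            g_up = g[:, :c_up]
            gsk = g[:, c_up : c_up + c_skip]
            g_ms = g[:, c_up + c_skip :]
            self.ms_convs[i].backward(self.ms_acts[i].backward(g_ms))
            gskips[s] = gsk.copy()
            g = self.up_convs[i].backward(
                self.up_acts[i].backward(self.shuffles[i].backward(g_up))
            )
        g = self.bottleneck.backward(g)
        for s in range(S - 1, -1, -1):
            g = self.downs[s].backward(self.down_acts[s].backward(g))
            g = g + gskips[s]
            g = self.enc_blocks[s].backward(g)
        self.stem.backward(self.stem_act.backward(g))


class Discriminator(Module):
    """Patch discriminator: five 3x3 convolutions, sigmoid patch scores."""

    def __init__(self, config: DiscriminatorConfig):
        rng = np.random.default_rng(config.seed)
        self.config = config
        widths = (config.in_channels,) + tuple(config.channels) + (1,)
        self.convs = [
            Conv2d(widths[i], widths[i + 1], 3, stride=config.strides[i], rng=rng)
            for i in range(5)
        ]
        self.acts = [LeakyReLU(config.lrelu_slope) for _ in range(4)]
        self.out_act = Sigmoid()

    def forward(self, x, train: bool = True):
        h = x
        for i in range(4):
            h = self.acts[i].forward(self.convs[i].forward(h, train), train)
        return self.out_act.forward(self.convs[4].forward(h, train), train)

    def backward(self, gy):
        g = self.convs[4].backward(self.out_act.backward(gy))
        for i in range(3, -1, -1):
            g = self.convs[i].backward(self.acts[i].backward(g))
        return g


# Calibrated so the parameter counts land on the architecture budgets of
# ~7.6e6 (generator) and ~1.6e6 (discriminator); see scripts/calibrate_model.py.
REFERENCE_GENERATOR = GeneratorConfig()
REFERENCE_DISCRIMINATOR = DiscriminatorConfig()


def build_generator(config: GeneratorConfig | None = None) -> Generator:
    """Instantiate a generator (He-normal initialized, seeded by the config)."""
    return Generator(config or REFERENCE_GENERATOR)


def build_discriminator(config: DiscriminatorConfig | None = None) -> Discriminator:
    return Discriminator(config or REFERENCE_DISCRIMINATOR)


def count_parameters(network: Module) -> int:
    """Total number of trainable scalar parameters."""
    return network.n_parameters()
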