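#!/usr/bin/env python
"""Calibrate reference architecture widths against the parameter budgets.

Scans (base_channels, growth_rate, ms_channels) for the generator and the
first-layer width for the discriminator, printing every configuration whose
trainable-parameter count lands within the target windows (7.6e6 and 1.6e6,
2% tolerance). The reference configurations in ``biraster.model`` were
frozen from this scan:

    generator      base 36, growth 17, ms 16  -> 7,599,365 parameters
    discriminator  widths (65, 130, 260, 520) -> 1,603,291 parameters

Usage: python scripts/calibrate_model.py
"""

from __future__ import annotations

import itertools

from biraster.model import (
    DiscriminatorConfig,
    GeneratorConfig,
    build_discriminator,
    build_generator,
    count_parameters,
)

GEN_TARGET = 7.6e6
DISC_TARGET = 1.6e6
TOL = 0.02


def main() -> None:
    print("# generator candidates (n_scales=3, dense_layers=4)")
    hits = []
    for base, growth, ms in itertools.product(
        range(30, 45), range(10, 20), (8, 12, 16, 20)
    ):
        cfg = GeneratorConfig(
            n_scales=3,
            dense_layers_per_block=4,
            growth_rate=growth,
            base_channels=base,
            ms_channels=ms,
        )
        n = count_parameters(build_generator(cfg))
        if abs(n - GEN_TARGET) / GEN_TARGET < TOL:
            hits.append((abs(n - GEN_TARGET), base, growth, ms, n))
    for _, base, growth, ms, n in sorted(hits)[:10]:
        print(f"base={base:3d} growth={growth:3d} ms={ms:3d} -> {n:,}")

    print("\n# discriminator candidates (doubling widths, 5 layers)")
    for c1 in range(58, 72):
        cfg = DiscriminatorConfig(channels=(c1, 2 * c1, 4 * c1, 8 * c1))
        n = count_parameters(build_discriminator(cfg))
        flag = " <-- in window" if abs(n - DISC_TARGET) / DISC_TARGET < TOL else ""
        print(f"c1={c1:3d} -> {n:,}{flag}")


if __name__ == "__main__":
    main()
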