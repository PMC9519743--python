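"""Closed-form system numbers: optical/acoustic resolution and data splits.

These are the analytically forced quantities of the imaging system the
simulator emulates: the diffraction-limited lateral resolution of the
excitation optics, the bandwidth-limited axial resolution of the
ultrasound detection, and the dataset split protocol.
"""

from biraster.preprocess import split_dataset
from biraster.simulate import (
    theoretical_axial_resolution,
    theoretical_lateral_resolution,
)

lat = theoretical_lateral_resolution(na=0.032, wavelength_nm=532)
axi = theoretical_axial_resolution(center_freq_mhz=20, fractional_bandwidth=0.60)
print(f"lateral resolution  0.51*lambda/NA      = {lat:.1f} um")
print(f"axial resolution    0.88*c/(f0*BW)      = {axi:.0f} um")

split = split_dataset(1154, test_frac=0.2, val_frac=0.1, seed=0)
print(
    f"split of 1154 pairs (8:2 then 9:1, ceiling): "
    f"{len(split.train)} train / {len(split.validation)} validation / {len(split.test)} test"
)
# Expected output: 8.5 um, 113 um, 830/93/231 — the ceiling rule is the
# unique rounding that reproduces both held-out counts.
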