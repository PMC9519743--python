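"""Independent brute-force reference implementations used as oracles."""

import numpy as np


def naive_ssim(a, b, data_range=1.0):
    """Sliding-window reference implementation (valid windows only)."""
    k = np.arange(11) - 5
    g = np.exp(-0.5 * (k / 1.5) ** 2)
    w = np.outer(g, g)
    w /= w.sum()
    C1, C2 = (0.01 * data_range) ** 2, (0.03 * data_range) ** 2
    vals = []
    for i in range(a.shape[0] - 10):
        for j in range(a.shape[1] - 10):
            wa, wb = a[i : i + 11, j : j + 11], b[i : i + 11, j : j + 11]
            mx, my = (w * wa).sum(), (w * wb).sum()
            sxx = (w * wa * wa).sum() - mx * mx
            syy = (w * wb * wb).sum() - my * my
            sxy = (w * wa * wb).sum() - mx * my
            vals.append(
                ((2 * mx * my + C1) * (2 * sxy + C2))
                / ((mx * mx + my * my + C1) * (sxx + syy + C2))
            )
    return float(np.mean(vals))
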