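"""Independent brute-force oracles used by the test suite only."""

import numpy as np
from skimage.measure import label as sk_label


def tfce_bruteforce(stat: np.ndarray, E: float, H: float, dh: float) -> np.ndarray:
    """Per-threshold connected-component labelling TFCE.

    Deliberately independent of the package implementation: relabels the
    supra-threshold set from scratch at every height with scikit-image.
    """
    out = np.zeros_like(stat, dtype=float)
    hmax = float(stat.max())
    if hmax <= 0:
        return out
    K = int(np.floor(hmax / dh + 1e-12))
    for k in range(1, K + 1):
        h = k * dh
        lab = sk_label(stat >= h, connectivity=3)
        if lab.max() == 0:
            continue
        sizes = np.bincount(lab.ravel())
        out += np.where(lab > 0, sizes[lab] ** E * h**H * dh, 0.0)
    return out
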