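import numpy as np
import pytest
from scipy import ndimage

from fearvox import design


@pytest.fixture(scope="session")
def default_schedule():
    return design.build_trial_sequence(counterbalance_seed=0)


@pytest.fixture(scope="session")
def hrf():
    return design.hrf_double_gamma(0.1)


def tfce_bruteforce(statmap, E=0.5, H=2.0, n_steps=100, connectivity=26):
    """Independent TFCE oracle: label suprathreshold components with
    scipy.ndimage at every threshold of the ladder and accumulate
    size^E * h^H * dh per member voxel."""
    s = np.maximum(np.asarray(statmap, dtype=float), 0.0)
    out = np.zeros_like(s)
    vmax = s.max()
    if vmax <= 0:
        return out
    dh = vmax / n_steps
    rank = {6: 1, 18: 2, 26: 3}[connectivity]
    struct = ndimage.generate_binary_structure(3, rank)
    for k in range(1, n_steps + 1):
        h = k * dh
        supra = s >= h
        labels, _ = ndimage.label(supra, structure=struct)
        sizes = np.bincount(labels.ravel())
        out += np.where(supra, sizes[labels] ** E * h**H * dh, 0.0)
    return out
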