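import numpy as np
import pytest

import vegrange as vr


@pytest.fixture(scope="session")
def grid40():
    return vr.make_grid(40, 48)


@pytest.fixture(scope="session")
def super_world(grid40):
    return vr.make_supercontinent(grid40, 0.3, 0.0, seed=1)


@pytest.fixture(scope="session")
def dispersed_world(grid40):
    return vr.make_dispersed(grid40, 0.3, 4, seed=1)


@pytest.fixture(scope="session")
def forcing():
    return vr.ForcingState()


@pytest.fixture(scope="session")
def coupler_config():
    return vr.CouplerConfig()


@pytest.fixture(scope="session")
def calibrated(dispersed_world, coupler_config):
    """Model parameters calibrated so the dispersed world balances at RCO2=1."""
    return vr.calibrate_reference(dispersed_world, vr.ModelParams(), coupler_config)


def periodic_component_count(mask: np.ndarray) -> int:
    """Independent connected-component oracle: scipy labeling + seam merge."""
    from scipy import ndimage

    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return 0
    parent = list(range(n + 1))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in zip(labels[:, 0], labels[:, -1]):
        if a and b:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
    return len({find(k) for k in range(1, n + 1) if (labels == k).any()})
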