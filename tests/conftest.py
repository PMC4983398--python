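import numpy as np
import pytest

import octlbp as ol


@pytest.fixture(scope="session")
def noiseless_spec() -> ol.PhantomSpec:
    """Default-geometry phantom with speckle disabled."""
    return ol.PhantomSpec(speckle_shape=None)


@pytest.fixture(scope="session")
def noiseless_dme(noiseless_spec):
    """One noise-free DME volume plus its ground truth."""
    return ol.generate_volume(noiseless_spec, "DME", seed=7)


@pytest.fixture(scope="session")
def noisy_dme():
    """One speckled DME volume plus spec and ground truth."""
    spec = ol.PhantomSpec()
    vol, truth = ol.generate_volume(spec, "DME", seed=3)
    return vol, truth, spec


def band_bottom_rows(bscan: np.ndarray, background: float) -> np.ndarray:
    """Bottom-most above-background row per column of a noise-free B-scan."""
    fg = bscan > background + 1e-9
    return bscan.shape[0] - 1 - np.argmax(fg[::-1, :], axis=0)
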