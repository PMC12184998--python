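import numpy as np
import pytest

import rotcam as rc


@pytest.fixture(scope="session")
def caf2_detector():
    return rc.build_detector(W=10.0, material="CaF2")


@pytest.fixture(scope="session")
def run208(caf2_detector):
    """Shared 208 keV point-source run (3000 ordered events, CsI resolution)."""
    return rc.simulate_point_source(
        caf2_detector, 208.0, target_ordered=3000, seed=20820,
        resolution=rc.CSI_MEASURED,
    )


@pytest.fixture(scope="session")
def sky208(run208, caf2_detector):
    """Sharpening-kernel reconstruction of the shared 208 keV run."""
    return rc.backproject(run208.ordered, caf2_detector, rc.KernelConfig("sharpening", 8.0, 1.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
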