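import numpy as np
import pytest

from ensemblepipe import Raster, generate_raster, preset


@pytest.fixture
def tiny_raster() -> Raster:
    """3 neurons x 6 frames, hand-written."""
    return Raster(
        np.array(
            [
                [1, 0, 1, 0, 1, 0],
                [1, 0, 1, 0, 0, 0],
                [0, 1, 0, 1, 0, 1],
            ]
        ),
        fps=4.0,
    )


@pytest.fixture(scope="session")
def control_raster_truth():
    """One control-like preset raster shared across tests (seed 11)."""
    return generate_raster(preset("control_like", seed=11))


@pytest.fixture(scope="session")
def control_raster(control_raster_truth):
    return control_raster_truth[0]
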