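import warnings

import numpy as np
import pytest

from synt1w import (
    PhantomSpec,
    SequenceParams,
    make_cord_phantom,
    synthesize_volume,
)
from synt1w.phantom import PD_CONTRAST_TISSUES

LEVELS_12 = {"C1": (0, 4), "C2": (4, 8), "C3": (8, 12)}


@pytest.fixture(scope="session")
def optimized_params() -> SequenceParams:
    """The calibration-optimal reconstruction setting (infeasible as an acquisition)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return SequenceParams.from_ms(14.0, 0.0, 1400.0, 900.0, 14.0, 176)


@pytest.fixture(scope="session")
def mprage_params() -> SequenceParams:
    """A conventional, physically realizable MPRAGE-like setting."""
    return SequenceParams.from_ms(9.0, 4.18, 2420.0, 960.0, 10.0, 176)


@pytest.fixture(scope="session")
def straight_phantom():
    """Noiseless untilted r=4 mm phantom with realistic (R1-contrast) tissues."""
    return make_cord_phantom(PhantomSpec(grid_shape=(48, 48, 16), cord_radius=4.0))


@pytest.fixture(scope="session")
def tilted_pd_phantom():
    """30-degree-tilted r=4 mm phantom with PD-only contrast (linear in fraction)."""
    return make_cord_phantom(
        PhantomSpec(
            grid_shape=(64, 64, 24),
            cord_radius=4.0,
            tilt_deg=30.0,
            tissue_params=dict(PD_CONTRAST_TISSUES),
        )
    )


@pytest.fixture(scope="session")
def straight_volume(straight_phantom, optimized_params) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return synthesize_volume(straight_phantom.maps, optimized_params)
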