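import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import simtempo as st

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# Reduced-scale microscope preserving the full-scale ratios: cutoff period
# N/cutoff = 4 px, fringe period 4.75 px (1.1875x the cutoff period).
DESK = dict(size=128, cutoff=32.0, fringe_period=4.75)


@pytest.fixture(scope="session")
def desk_otf():
    return st.make_otf(DESK["size"], DESK["cutoff"])


@pytest.fixture(scope="session")
def desk_patterns():
    return st.make_pattern_set(DESK["size"], DESK["fringe_period"])


@pytest.fixture(scope="session")
def desk_sample():
    return st.generate_point_sample(DESK["size"], 0.01, 1.0, seed=7)


@pytest.fixture(scope="session")
def tiny_otf():
    return st.make_otf(32, 8.0)


@pytest.fixture(scope="session")
def tiny_patterns():
    return st.make_pattern_set(32, 4.75)


def constant_stack(image: np.ndarray, n_frames: int) -> st.GroundTruthStack:
    """A ground-truth stack with literally constant (unmodulated) intensity."""
    trace = st.ModulationTrace(tm=np.inf, values=np.ones(n_frames))
    return st.GroundTruthStack(
        frames=np.repeat(image[None], n_frames, axis=0), trace=trace
    )
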