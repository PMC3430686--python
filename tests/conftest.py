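import numpy as np
import pytest

from dyadstate.eventlog import PairTrajectory, TransitionEvent


def make_trajectory(
    times_edges, duration=100.0, initial_state=1, pair_id="p1", session="control"
):
    events = [
        TransitionEvent(time=t, from_state=a, to_state=b) for t, (a, b) in times_edges
    ]
    return PairTrajectory(
        pair_id=pair_id,
        session=session,
        duration=duration,
        initial_state=initial_state,
        events=events,
    )


@pytest.fixture
def joint_trip_trajectory():
    """The worked example: 1 ->(5) 2 ->(10) 4 ->(50) 3 ->(60) 1, duration 100."""
    return make_trajectory(
        [(5.0, (1, 2)), (10.0, (2, 4)), (50.0, (4, 3)), (60.0, (3, 1))]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
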