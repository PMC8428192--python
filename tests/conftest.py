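import numpy as np
import pytest

from fraghr import NNSeries


def make_nn(intervals_ms, run_id=None, sf=256.0, t0=0.0):
    """Build an NNSeries with end times accumulated from the intervals."""
    intervals = np.asarray(intervals_ms, dtype=float)
    ends = t0 + np.cumsum(intervals) / 1000.0
    rid = (
        np.zeros(intervals.size, dtype=int)
        if run_id is None
        else np.asarray(run_id, dtype=int)
    )
    return NNSeries(
        intervals=intervals,
        end_times=ends,
        run_id=rid,
        sampling_frequency=sf,
        onset_s=t0,
        termination_s=float(ends[-1]),
    )


@pytest.fixture
def alternating_nn():
    """Alternating 1000/990 ms series spanning one full 5-min window."""
    vals = np.tile([1000.0, 990.0], 200)
    return make_nn(vals)


@pytest.fixture
def nn_factory():
    return make_nn
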