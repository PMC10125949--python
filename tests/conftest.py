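import numpy as np
import pytest

from earlyclick.io import Clickstream, Event
from earlyclick.synthetic import generate, preset


def make_stream(sid, actions, times, outcome=0, total_time=None):
    events = tuple(Event(a, float(t)) for a, t in zip(actions, times))
    if total_time is None:
        total_time = times[-1] if len(times) else 0.0
    return Clickstream(id=sid, events=events, outcome=outcome, total_time=float(total_time))


@pytest.fixture
def toy_streams():
    """Six small handcrafted streams with both outcomes."""
    return [
        make_stream("f1", ["A", "B", "A"], [2, 5, 9], outcome=1, total_time=12),
        make_stream("f2", ["B", "C"], [4, 40], outcome=1, total_time=45),
        make_stream("s1", ["A", "B", "C", "D", "E"], [1, 3, 8, 20, 33], outcome=0, total_time=35),
        make_stream("s2", ["C", "A", "D", "B", "E", "A"], [5, 10, 22, 31, 47, 60], outcome=0, total_time=70),
        make_stream("s3", ["D", "E", "A", "C"], [3, 12, 25, 44], outcome=0, total_time=50),
        make_stream("f3", ["A"], [6], outcome=1, total_time=8),
    ]


@pytest.fixture(scope="session")
def paper_like_streams():
    return generate(preset("paper-like", n_streams=400, seed=11))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
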