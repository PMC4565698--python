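import numpy as np
import pandas as pd
import pytest

from rankloop.events import AggressionMatrix, event_log_from_frame
from rankloop.ranking import RankOrder


def make_log(times, actors, targets, roster=None, t_obs_minutes=None):
    frame = pd.DataFrame({"time": times, "actor": actors, "target": targets})
    return event_log_from_frame(frame, roster=roster, t_obs_minutes=t_obs_minutes)


@pytest.fixture
def toy_log():
    """Five events among three birds over one day."""
    return make_log(
        [10.0, 70.0, 200.0, 300.0, 4000.0],
        ["A", "A", "B", "A", "C"],
        ["B", "B", "A", "C", "B"],
        roster=("A", "B", "C"),
        t_obs_minutes=1440.0,
    )


# Hand-checkable 4-bird matrix used across ranking tests:
#   A beats B 3x and C 1x; B beats A 1x and C 2x; C beats B 1x and D 4x;
#   D beats C 1x.
TOY4 = np.array(
    [
        [0, 3, 1, 0],
        [1, 0, 2, 0],
        [0, 1, 0, 4],
        [0, 0, 1, 0],
    ]
)


@pytest.fixture
def toy4_matrix():
    return AggressionMatrix(TOY4.copy(), ("A", "B", "C", "D"))


@pytest.fixture
def identity_order():
    """Rank order = roster order for a 4-bird group."""
    return RankOrder(("A", "B", "C", "D"), np.array([1, 2, 3, 4]))


def linear_hierarchy_matrix(n, wins=1):
    """Everyone attacks exactly the next-ranked individual `wins` times."""
    c = np.zeros((n, n), dtype=int)
    for i in range(n - 1):
        c[i, i + 1] = wins
    return AggressionMatrix(c, tuple(f"i{k}" for k in range(n)))


def random_agg_matrix(rng, n, max_count=6):
    c = rng.integers(0, max_count + 1, size=(n, n))
    np.fill_diagonal(c, 0)
    return AggressionMatrix(c, tuple(f"i{k}" for k in range(n)))
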