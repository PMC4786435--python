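import numpy as np
import pandas as pd
import pytest

from mbdim.rl import HybridParams
from mbdim.task import SessionData, TaskConfig, simulate_session


@pytest.fixture(scope="session")
def default_params():
    return HybridParams(0.5, 1.2, 0.7, 0.3, 0.5, 0.15)


@pytest.fixture(scope="session")
def short_session(default_params):
    return simulate_session(default_params, TaskConfig(n_trials=150), seed=42)


@pytest.fixture(scope="session")
def session_with_misses(default_params):
    return simulate_session(
        default_params, TaskConfig(n_trials=150), seed=43, miss_prob=0.07
    )


def make_session(rows, subject_id="toy"):
    """Build a SessionData from (c1, transition, state, c2, reward) tuples."""
    df = pd.DataFrame(rows, columns=["c1", "transition", "state", "c2", "reward"])
    df.insert(0, "t", np.arange(len(df)))
    df["missed"] = False
    df["rt"] = 0.5
    for c in ("p1", "p2", "p3", "p4"):
        df[c] = 0.5
    return SessionData(subject_id=subject_id, trials=df,
                       config=TaskConfig(n_trials=max(len(df), 2)))
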