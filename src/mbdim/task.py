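"""Generative model of the two-step sequential decision task.

Each trial has a binary first-stage choice that leads, through a fixed
70/30 probabilistic transition structure, to one of two second-stage
states; the second-stage choice is rewarded with a probability that
drifts across trials as a bounded Gaussian random walk.  Sessions are
played closed-loop by hybrid model-based / model-free agents
(:mod:`mbdim.rl`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from . import _kernels

TRIAL_COLUMNS = [
    "t", "c1", "transition", "state", "c2", "reward", "missed", "rt",
    "p1", "p2", "p3", "p4",
]


@dataclass(frozen=True)
class TaskConfig:
    """Structural parameters of the task.

    walk_step_sd is the per-trial standard deviation of the Gaussian
    increment of each reward-probability walk; proposed steps that leave
    ``walk_bounds`` are reflected off the boundary by default (set
    ``boundary="truncate"`` to clip instead).
    """

    n_trials: int = 200
    p_common: float = 0.7
    walk_bounds: tuple[float, float] = (0.25, 0.75)
    walk_step_sd: float = 0.025
    reward_value: float = 0.25  # cosmetic: dollars per rewarded trial
    boundary: str = "reflect"
    rng_seed: int | None = None

    def __post_init__(self):
        if self.n_trials < 2:
            raise ValueError("n_trials must be >= 2")
        if not 0.0 < self.p_common < 1.0:
            raise ValueError("p_common must lie in (0, 1)")
        lo, hi = self.walk_bounds
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("walk_bounds must satisfy 0 < lower < upper < 1")
        if self.walk_step_sd < 0:
            raise ValueError("walk_step_sd must be >= 0")
        if self.boundary not in ("reflect", "truncate"):
            raise ValueError("boundary must be 'reflect' or 'truncate'")


class TrialRecord(NamedTuple):
    t: int
    c1: int
    transition: str  # "common" | "rare"
    state: int
    c2: int
    reward: int
    reward_probs: tuple[float, float, float, float]
    missed: bool
    rt: float


@dataclass
class SessionData:
    """One subject's session: an ordered trial table plus its config."""

    subject_id: str
    trials: pd.DataFrame
    config: TaskConfig = field(default_factory=TaskConfig)

    def __post_init__(self):
        t = self.trials["t"].to_numpy()
        if len(t) and not np.array_equal(t, np.arange(len(t))):
            raise ValueError("trial indices must be contiguous from 0")

    def records(self):
        for row in self.trials.itertuples(index=False):
            yield TrialRecord(
                int(row.t), int(row.c1), row.transition, int(row.state),
                int(row.c2), int(row.reward),
                (row.p1, row.p2, row.p3, row.p4), bool(row.missed), row.rt,
            )

    def arrays(self):
        """(c1, state, c2, reward, missed) as int64/bool arrays for kernels."""
        tr = self.trials
        return (
            tr["c1"].to_numpy(dtype=np.int64),
            tr["state"].to_numpy(dtype=np.int64),
            tr["c2"].to_numpy(dtype=np.int64),
            tr["reward"].to_numpy(dtype=np.int64),
            tr["missed"].to_numpy(dtype=bool),
        )


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_walks(config: TaskConfig, seed=None) -> np.ndarray:
    """Simulate the four independent bounded Gaussian reward walks.

    Returns a (4, n_trials) matrix of reward probabilities; row index is
    2 * state + stage-2 choice.  Initial values are uniform within the
    bounds; each subsequent value adds a N(0, walk_step_sd) step, with
    excursions beyond the bounds reflected (or truncated).
    """
    rng = _as_rng(config.rng_seed if seed is None else seed)
    lo, hi = config.walk_bounds
    walks = np.empty((4, config.n_trials))
    walks[:, 0] = rng.uniform(lo, hi, size=4)
    steps = rng.normal(0.0, config.walk_step_sd, size=(4, config.n_trials - 1))
    for t in range(1, config.n_trials):
        prop = walks[:, t - 1] + steps[:, t - 1]
        if config.boundary == "reflect":
            # small steps need at most a few reflections
            for _ in range(16):
                over = prop > hi
                under = prop < lo
                if not (over.any() or under.any()):
                    break
                prop[over] = 2 * hi - prop[over]
                prop[under] = 2 * lo - prop[under]
        walks[:, t] = np.clip(prop, lo, hi)
    return walks


def simulate_session(
    params,
    config: TaskConfig | None = None,
    seed=None,
    subject_id: str = "sim",
    miss_prob: float = 0.0,
    rt_mean: float = 0.7,
    rt_sd: float = 0.15,
    q_init: float = 0.0,
    mf0_uses_updated_stage2: bool = True,
    walks: np.ndarray | None = None,
) -> SessionData:
    """Closed-loop simulation of one session by a hybrid agent.

    ``params`` is an :class:`mbdim.rl.HybridParams`.  Choices are sampled
    from the hybrid softmax policy, transitions with probability
    ``p_common``, rewards from the current walk; the agent state is
    updated by the model's delta rules after every completed trial.
    Reaction times are cosmetic lognormal draws (no RT model is implied).
    """
    config = config or TaskConfig()
    rng = _as_rng(seed)
    if walks is None:
        walks = simulate_walks(config, rng)
    theta = params.as_array()
    u = rng.random((config.n_trials, 5))
    c1, s, c2, r, missed = _kernels.simulate_trials(
        theta, walks, config.p_common, u, miss_prob, q_init,
        mf0_uses_updated_stage2,
    )
    rt = rng.lognormal(np.log(rt_mean), rt_sd, size=config.n_trials)
    rt[missed] = np.nan
    trials = pd.DataFrame(
        {
            "t": np.arange(config.n_trials),
            "c1": c1,
            "transition": np.where(
                missed, "missed", np.where(s == c1, "common", "rare")
            ),
            "state": s,
            "c2": c2,
            "reward": r,
            "missed": missed,
            "rt": rt,
            "p1": walks[0],
            "p2": walks[1],
            "p3": walks[2],
            "p4": walks[3],
        }
    )
    return SessionData(subject_id=subject_id, trials=trials, config=config)


def sessions_to_frame(sessions: Sequence[SessionData]) -> pd.DataFrame:
    """Concatenate sessions into one long trial-log table."""
    frames = []
    for s in sessions:
        df = s.trials.copy()
        df.insert(0, "subject_id", s.subject_id)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def frame_to_sessions(df: pd.DataFrame, config: TaskConfig | None = None):
    """Split a long trial-log table back into per-subject sessions."""
    config = config or TaskConfig()
    out = []
    for sid, grp in df.groupby("subject_id", sort=False):
        trials = grp.drop(columns=["subject_id"]).reset_index(drop=True)
        cfg = replace(config, n_trials=len(trials))
        out.append(SessionData(subject_id=str(sid), trials=trials, config=cfg))
    return out


def write_trials_csv(sessions: Sequence[SessionData], path) -> None:
    sessions_to_frame(sessions).to_csv(path, index=False)


def read_trials_csv(path, config: TaskConfig | None = None):
    df = pd.read_csv(path)
    df["missed"] = df["missed"].astype(bool)
    return frame_to_sessions(df, config)
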