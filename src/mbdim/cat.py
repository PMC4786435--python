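"""Compact computerized adaptive test (CAT) under the 2PL IRT model.

Item response probability P(correct) = 1 / (1 + exp(-a (theta - b)));
items are selected by Maximum Fisher Information with randomesque
exposure control (uniform draw among the top 3 most informative
unadministered items) and ability is re-estimated after each response by
the Bayes modal (posterior mode) estimator under a standard-normal
prior.  The first administered item is a fixed non-diagnostic starter
contributing no likelihood term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

BANK_COLUMNS = ["item_id", "a", "b"]


def p_correct(theta, a, b):
    """2PL correct-response probability."""
    return expit(np.asarray(a) * (np.asarray(theta) - np.asarray(b)))


def info(theta, a, b):
    """Fisher information of an item at ability theta: a^2 P (1-P)."""
    p = p_correct(theta, a, b)
    return np.asarray(a) ** 2 * p * (1.0 - p)


def make_bank(
    n_items: int = 26, seed=None, a_log_sd: float = 0.5477225575051661,
    b_sd: float = 1.0,
) -> pd.DataFrame:
    """Synthetic 2PL item bank.

    Discriminations are lognormal with log-mean 0 and log-variance 0.3
    (``a_log_sd`` is the log-scale SD, sqrt(0.3)); difficulties are
    N(0, b_sd).  The defaults emulate a screened progressive-matrices
    style bank whose items discriminate well.
    """
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "item_id": [f"item{i:02d}" for i in range(n_items)],
            "a": rng.lognormal(0.0, a_log_sd, n_items),
            "b": rng.normal(0.0, b_sd, n_items),
        }
    )


def bayes_modal(responses, a, b, prior_sd: float | None = 1.0,
                max_iter: int = 50, tol: float = 1e-8) -> float:
    """Posterior mode of theta given a 2PL response pattern.

    ``prior_sd=None`` drops the prior, giving the ML estimate where it
    exists.  Newton iteration with a grid-search fallback when the
    likelihood is flat or the iteration leaves a plausible range.
    """
    r = np.asarray(responses, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(r) == 0:
        return 0.0

    def score_hess(t):
        p = expit(a * (t - b))
        g = np.sum(a * (r - p))
        h = -np.sum(a**2 * p * (1 - p))
        if prior_sd is not None:
            g -= t / prior_sd**2
            h -= 1.0 / prior_sd**2
        return g, h

    t = 0.0
    ok = False
    for _ in range(max_iter):
        g, h = score_hess(t)
        if h >= 0:
            break
        step = g / h
        t_new = t - step
        if abs(t_new) > 10:
            break
        if abs(t_new - t) < tol:
            t = t_new
            ok = True
            break
        t = t_new
    if not ok:
        grid = np.arange(-6.0, 6.0 + 1e-9, 0.001)
        p = expit(np.outer(grid, a) - a * b)
        ll = (r * np.log(np.clip(p, 1e-12, 1)) +
              (1 - r) * np.log(np.clip(1 - p, 1e-12, 1))).sum(axis=1)
        if prior_sd is not None:
            ll -= 0.5 * grid**2 / prior_sd**2
        t = float(grid[np.argmax(ll)])
    return float(t)


@dataclass
class CatSession:
    administered: list = field(default_factory=list)  # item ids, in order
    responses: list = field(default_factory=list)     # 0/1 incl. starter
    theta_path: list = field(default_factory=list)    # estimate after each item
    starter_id: str | None = None

    @property
    def theta(self) -> float:
        return self.theta_path[-1] if self.theta_path else 0.0

    @property
    def n_correct(self) -> int:
        """Correct scored (non-starter) responses."""
        return int(sum(self.responses[1:])) if self.starter_id else int(sum(self.responses))


def administer_cat(
    bank: pd.DataFrame,
    true_theta: float | None = None,
    length: int = 5,
    randomesque: int = 3,
    seed=None,
    responder=None,
) -> CatSession:
    """Run one adaptive test of ``length`` scored items plus the starter.

    Responses are simulated from ``true_theta`` under the 2PL model unless
    a ``responder(item_row) -> 0/1`` callable is given.  At every step the
    unadministered items are ranked by Fisher information at the current
    estimate and the next item is drawn uniformly among the top
    ``randomesque``.
    """
    rng = np.random.default_rng(seed)
    if len(bank) < length + randomesque:
        raise ValueError("item bank too small for requested test length")
    if responder is None:
        if true_theta is None:
            raise ValueError("provide true_theta or a responder callable")
        responder = lambda row: int(rng.random() < p_correct(true_theta, row.a, row.b))

    bank = bank.reset_index(drop=True)
    available = set(bank.index)
    session = CatSession()
    theta_hat = 0.0

    # fixed non-diagnostic starter: the most informative item at theta = 0
    start = int(bank.index[np.argmax(info(0.0, bank["a"], bank["b"]))])
    session.starter_id = bank.loc[start, "item_id"]
    session.administered.append(session.starter_id)
    session.responses.append(responder(bank.loc[start]))
    session.theta_path.append(theta_hat)  # starter adds no likelihood term
    available.discard(start)

    scored_a, scored_b, scored_r = [], [], []
    for _ in range(length):
        if not available:
            raise ValueError("item bank exhausted")
        idx = np.array(sorted(available))
        infos = np.asarray(info(theta_hat, bank.loc[idx, "a"], bank.loc[idx, "b"]))
        top = idx[np.argsort(infos)[::-1][: min(randomesque, len(idx))]]
        choice = int(rng.choice(top))
        available.discard(choice)
        row = bank.loc[choice]
        resp = responder(row)
        session.administered.append(row["item_id"])
        session.responses.append(resp)
        scored_a.append(row["a"])
        scored_b.append(row["b"])
        scored_r.append(resp)
        theta_hat = bayes_modal(scored_r, scored_a, scored_b)
        session.theta_path.append(theta_hat)
    return session


def ml_full_bank_score(responses, bank: pd.DataFrame) -> float:
    """ML ability estimate from a full-bank response pattern (flat prior)."""
    return bayes_modal(responses, bank["a"], bank["b"], prior_sd=None)
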