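"""Hybrid model-based / model-free reinforcement-learning model.

Value learning
--------------
At stage 2 the chosen state-action value follows a delta rule
``Q2(s_t, c2_t) <- (1 - alpha) Q2 + r_t``.  Stage-1 model-free values are
learned by two rules with different targets: TD(0)
(``QMF0(c1_t) <- (1 - alpha) QMF0 + Q2(s_t, c2_t)``) and TD(1)
(``QMF1(c1_t) <- (1 - alpha) QMF1 + r_t``).  Model-based values take the
learned stage-2 values of the state predominantly produced by each
stage-1 choice, maximized over the two stage-2 actions.  At the end of
every trial all unchosen actions and unvisited states decay
multiplicatively by ``(1 - alpha)``.  The learning-rate factor is
deliberately omitted from each innovation term -- a change of variables
that rescales the Qs and their weights and removes the eligibility-trace
parameter; the aggregate model-free weight is reconstructed afterwards as
``beta_MF = beta_MF0 + alpha * beta_MF1``.

Choice
------
Stage-1 choice probabilities are a softmax over
``beta_MB QMB + beta_MF0 QMF0 + beta_MF1 QMF1 + beta_stick I(c = prev)``;
stage-2 probabilities a softmax over ``beta_stage2 Q2(s, .)``.

Fitting
-------
:class:`HybridEM` estimates per-subject parameters jointly with a
Gaussian group-level prior (diagonal, alpha on the log-odds scale) by
Expectation-Maximization with Laplace-approximate E-steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit
from sklearn.base import BaseEstimator

from . import _kernels

PARAM_NAMES = ["alpha", "beta_stage2", "beta_mb", "beta_mf0", "beta_mf1", "beta_stick"]


@dataclass(frozen=True)
class HybridParams:
    """The model's six free parameters; ``beta_mf`` is derived, never stored."""

    alpha: float = 0.5
    beta_stage2: float = 1.0
    beta_mb: float = 1.0
    beta_mf0: float = 0.5
    beta_mf1: float = 0.5
    beta_stick: float = 0.1

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie strictly in (0, 1)")

    @property
    def beta_mf(self) -> float:
        return self.beta_mf0 + self.alpha * self.beta_mf1

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.alpha, self.beta_stage2, self.beta_mb,
             self.beta_mf0, self.beta_mf1, self.beta_stick]
        )

    @classmethod
    def from_array(cls, theta) -> "HybridParams":
        return cls(*[float(x) for x in theta])


@dataclass
class AgentState:
    """Learner state carried across trials."""

    q_stage2: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))
    q_mf0: np.ndarray = field(default_factory=lambda: np.zeros(2))
    q_mf1: np.ndarray = field(default_factory=lambda: np.zeros(2))
    prev_c1: int | None = None

    @property
    def q_mb(self) -> np.ndarray:
        # value of each stage-1 choice = max stage-2 value of the state it
        # predominantly produces (fixed mapping: choice c -> state c)
        return self.q_stage2.max(axis=1)


def hybrid_policy(params: HybridParams, state: AgentState, stage: int, s: int | None = None):
    """Choice probabilities at the given stage; always a proper softmax."""
    if stage == 1:
        v = (
            params.beta_mb * state.q_mb
            + params.beta_mf0 * state.q_mf0
            + params.beta_mf1 * state.q_mf1
        )
        if state.prev_c1 is not None:
            v = v + params.beta_stick * np.eye(2)[state.prev_c1]
    elif stage == 2:
        if s not in (0, 1):
            raise ValueError("stage-2 state must be 0 or 1")
        v = params.beta_stage2 * state.q_stage2[s]
    else:
        raise ValueError("stage must be 1 or 2")
    v = v - v.max()
    e = np.exp(v)
    return e / e.sum()


def step_update(
    state: AgentState,
    trial,
    alpha: float,
    mf0_uses_updated_stage2: bool = True,
) -> AgentState:
    """Apply one trial's delta rules and decay; returns a new AgentState.

    ``trial`` needs attributes c1, state, c2, reward, missed.  By default
    the TD(0) target is the stage-2 value *after* that trial's stage-2
    update (the update equations are applied in listing order); pass
    ``mf0_uses_updated_stage2=False`` to use the pre-update value.
    """
    if getattr(trial, "missed", False):
        return state
    a1, st, a2, rew = int(trial.c1), int(trial.state), int(trial.c2), float(trial.reward)
    q2 = state.q_stage2.copy()
    qmf0 = state.q_mf0.copy()
    qmf1 = state.q_mf1.copy()
    d = 1.0 - alpha
    q2_pre = q2[st, a2]
    q2 *= d
    q2[st, a2] = d * q2_pre + rew
    target = q2[st, a2] if mf0_uses_updated_stage2 else q2_pre
    qmf0 *= d
    qmf0[a1] = d * state.q_mf0[a1] + target
    qmf1 *= d
    qmf1[a1] = d * state.q_mf1[a1] + rew
    return AgentState(q_stage2=q2, q_mf0=qmf0, q_mf1=qmf1, prev_c1=a1)


def session_loglik(
    params: HybridParams,
    session,
    q_init: float = 0.0,
    mf0_uses_updated_stage2: bool = True,
) -> float:
    """Log-likelihood of a session's observed choices under the model."""
    theta = params.as_array() if isinstance(params, HybridParams) else np.asarray(params, float)
    if np.any(~np.isfinite(theta)):
        raise ValueError("parameters must be finite")
    c1, s, c2, r, missed = session.arrays()
    ll, _ = _kernels.loglik_grad(theta, c1, s, c2, r, missed, q_init, mf0_uses_updated_stage2)
    return float(ll)


def session_loglik_grad(params, session, q_init=0.0, mf0_uses_updated_stage2=True):
    """(log-likelihood, gradient) w.r.t. raw (alpha, beta...) parameters."""
    theta = params.as_array() if isinstance(params, HybridParams) else np.asarray(params, float)
    c1, s, c2, r, missed = session.arrays()
    ll, g = _kernels.loglik_grad(theta, c1, s, c2, r, missed, q_init, mf0_uses_updated_stage2)
    return float(ll), g


@dataclass
class GroupPrior:
    """Diagonal Gaussian prior over transformed parameters.

    alpha lives on the log-odds scale; the five weights are untransformed.
    """

    mean: np.ndarray
    var: np.ndarray
    names: tuple = ("alpha_logit", "beta_stage2", "beta_mb", "beta_mf0", "beta_mf1", "beta_stick")

    def __post_init__(self):
        self.mean = np.asarray(self.mean, float)
        self.var = np.asarray(self.var, float)
        if np.any(self.var <= 0):
            raise ValueError("prior variances must be > 0")


def to_transformed(theta_raw: np.ndarray) -> np.ndarray:
    x = np.array(theta_raw, float)
    x[0] = logit(x[0])
    return x


def to_raw(x: np.ndarray) -> np.ndarray:
    theta = np.array(x, float)
    theta[0] = expit(theta[0])
    return theta


class HybridEM(BaseEstimator):
    """Hierarchical EM fitter for the hybrid model.

    E-step: per-subject MAP estimate of the transformed parameters under
    the current Gaussian prior (L-BFGS with analytic gradients, several
    random restarts, Laplace covariance from a finite-difference Hessian).
    M-step: prior mean from the MAP estimates; prior variance from the
    second moments including the Laplace uncertainty.  Iterates until the
    prior means move less than ``tol``.

    Attributes (after fit): ``subjects_`` (per-subject MAP parameters and
    the derived beta_mf), ``prior_``, ``objective_trace_``, ``n_iter_``,
    ``converged_``.
    """

    def __init__(
        self,
        max_iter: int = 100,
        tol: float = 1e-4,
        n_restarts: int = 5,
        q_init: float = 0.0,
        mf0_uses_updated_stage2: bool = True,
        prior_mean=None,
        prior_var=None,
        no_pooling: bool = False,
        random_state: int | None = 0,
    ):
        self.max_iter = max_iter
        self.tol = tol
        self.n_restarts = n_restarts
        self.q_init = q_init
        self.mf0_uses_updated_stage2 = mf0_uses_updated_stage2
        self.prior_mean = prior_mean
        self.prior_var = prior_var
        self.no_pooling = no_pooling
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _neg_posterior(self, x, data, mean, var):
        theta = to_raw(x)
        ll, g = _kernels.loglik_grad(
            theta, *data, self.q_init, self.mf0_uses_updated_stage2
        )
        # chain rule through alpha = expit(x0)
        g = g.copy()
        g[0] *= theta[0] * (1.0 - theta[0])
        if self.no_pooling:
            return -ll, -g
        resid = x - mean
        return -(ll - 0.5 * np.sum(resid**2 / var)), -(g - resid / var)

    def _map_one(self, data, mean, var, noise):
        best = None
        x0s = [mean.copy()]
        for row in noise:
            x0s.append(mean + row * np.sqrt(np.minimum(var, 4.0)))
        for x0 in x0s:
            res = minimize(
                self._neg_posterior, x0, args=(data, mean, var),
                jac=True, method="L-BFGS-B",
                options={"maxiter": 300, "ftol": 1e-10, "gtol": 1e-7},
            )
            if best is None or res.fun < best.fun:
                best = res
        # Laplace variance from central finite differences of the gradient
        x = best.x
        n = len(x)
        H = np.zeros((n, n))
        h = 1e-4
        for j in range(n):
            xp = x.copy(); xp[j] += h
            xm = x.copy(); xm[j] -= h
            _, gp = self._neg_posterior(xp, data, mean, var)
            _, gm = self._neg_posterior(xm, data, mean, var)
            H[:, j] = (gp - gm) / (2 * h)
        H = 0.5 * (H + H.T)
        try:
            cov = np.linalg.inv(H)
            # a proper posterior is never wider than its prior; clip the
            # Laplace variances accordingly (the numerical Hessian can be
            # near-singular along weakly identified directions)
            lapvar = np.clip(np.diag(cov), 1e-8, var)
            _, logdet = np.linalg.slogdet(H)
        except np.linalg.LinAlgError:
            lapvar = var.copy()
            logdet = 0.0
        # Laplace approximation to the marginal likelihood of this subject
        # (includes the prior normalizing constant so the EM objective is
        # comparable across M-step updates of the variances)
        prior_norm = 0.0 if self.no_pooling else -0.5 * np.sum(np.log(2 * np.pi * var))
        laplace_ml = -best.fun + prior_norm + 0.5 * n * np.log(2 * np.pi) - 0.5 * logdet
        return x, lapvar, laplace_ml

    # -- API ---------------------------------------------------------------

    def fit(self, sessions):
        rng = np.random.default_rng(self.random_state)
        data = [s.arrays() for s in sessions]
        ids = [s.subject_id for s in sessions]
        mean = (
            np.asarray(self.prior_mean, float)
            if self.prior_mean is not None
            else np.array([0.0, 0.5, 0.5, 0.2, 0.2, 0.0])
        )
        var = (
            np.asarray(self.prior_var, float)
            if self.prior_var is not None
            else np.full(6, 4.0)
        )
        # restart perturbations are drawn once so that repeated E-steps are
        # deterministic and the EM trajectory does not jitter across iterations
        noise = rng.normal(size=(len(data), max(0, self.n_restarts - 1), 6))
        trace = []
        converged = False
        maps = None
        for it in range(self.max_iter):
            out = [
                self._map_one(d, mean, var, nz) for d, nz in zip(data, noise)
            ]
            maps = np.array([o[0] for o in out])
            lapvars = np.array([o[1] for o in out])
            trace.append(float(sum(o[2] for o in out)))
            if self.no_pooling:
                converged = True
                break
            new_mean = maps.mean(axis=0)
            new_var = np.clip(
                (maps**2 + lapvars).mean(axis=0) - new_mean**2, 1e-4, None
            )
            shift = np.max(np.abs(new_mean - mean))
            mean, var = new_mean, new_var
            if shift < self.tol:
                converged = True
                break
        if not converged and not self.no_pooling:
            warnings.warn("EM did not converge within max_iter; returning best fit")
        raw = np.array([to_raw(m) for m in maps])
        self.subjects_ = pd.DataFrame(raw, columns=PARAM_NAMES, index=pd.Index(ids, name="subject_id"))
        self.subjects_["beta_mf"] = (
            self.subjects_["beta_mf0"] + self.subjects_["alpha"] * self.subjects_["beta_mf1"]
        )
        self.map_transformed_ = maps
        self.laplace_var_ = lapvars
        self.prior_ = GroupPrior(mean=mean, var=var)
        self.objective_trace_ = np.array(trace)
        self.n_iter_ = len(trace)
        self.converged_ = converged
        return self

    @property
    def prior_se_(self):
        """Posterior SE of each group mean (prior sd / sqrt(n_subjects))."""
        return np.sqrt(self.prior_.var / len(self.subjects_))


def fit_em(sessions, **kwargs) -> HybridEM:
    """Fit the hierarchical model; see :class:`HybridEM`."""
    return HybridEM(**kwargs).fit(sessions)


def extract_indices(fits) -> pd.DataFrame:
    """Per-subject model-based and model-free weights from a fit.

    Accepts a fitted :class:`HybridEM` or its ``subjects_`` table; the
    aggregate model-free weight uses the reconstruction identity
    ``beta_mf = beta_mf0 + alpha * beta_mf1``.
    """
    table = fits.subjects_ if isinstance(fits, HybridEM) else fits
    out = table[["beta_mb"]].copy()
    out["beta_mf"] = table["beta_mf0"] + table["alpha"] * table["beta_mf1"]
    return out
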