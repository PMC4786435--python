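"""Supervised item selection: elastic net with nested CV and stability.

Identifies questionnaire items predicting the (covariate-residualized)
model-based index.  Hyperparameters are tuned on a 50 x 50
(l1-ratio x penalty) grid by 10-fold inner cross-validation inside each
of 10 outer folds; the whole procedure is repeated over re-randomized
fold splits and items are retained when selected in at least 95% of
iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.base import BaseEstimator
from sklearn.linear_model import ElasticNet, LinearRegression
from sklearn.model_selection import KFold

_SCALE_TOL = 1e-6


@dataclass(frozen=True)
class EnetConfig:
    """Grid and resampling settings of the stability analysis."""

    n_alpha: int = 50
    alpha_range: tuple[float, float] = (0.01, 1.0)
    n_lambda: int = 50
    lambda_range: tuple[float, float] = (1e-4, 1.0)
    outer_folds: int = 10
    inner_folds: int = 10
    n_iterations: int = 100
    retention_threshold: float = 0.95
    aggregation: str = "majority"  # or "all": nonzero in every outer fold
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.retention_threshold <= 1):
            raise ValueError("retention threshold must lie in (0, 1]")
        lo, hi = self.alpha_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("alpha grid must lie within (0, 1]")
        if self.lambda_range[0] <= 0:
            raise ValueError("lambda grid must be positive")

    @property
    def alphas(self) -> np.ndarray:
        return np.linspace(*self.alpha_range, self.n_alpha)

    @property
    def lambdas(self) -> np.ndarray:
        # log spacing, descending for warm starts
        return np.geomspace(self.lambda_range[1], self.lambda_range[0], self.n_lambda)


@dataclass
class StabilityResult:
    retention_frequency: pd.Series
    retained: list
    cv_r: np.ndarray
    cv_p: np.ndarray
    median_r: float = field(init=False)
    median_p: float = field(init=False)

    def __post_init__(self):
        self.median_r = float(np.median(self.cv_r))
        self.median_p = float(np.median(self.cv_p))


def _check_scaled(X, y, tol=0.05):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    sd = X.std(axis=0, ddof=0)
    if np.any(np.abs(sd - 1.0) > tol):
        raise ValueError("X must be feature-scaled (z-scored) column-wise")
    if abs(y.mean()) > 1e-8 * max(1.0, np.abs(y).max()):
        y = y - y.mean()
    return X, y


def _enet(X, y, alpha, lam):
    """Unchecked solver (used on CV subsamples of an already-scaled X)."""
    if lam == 0:
        return LinearRegression(fit_intercept=False).fit(X, y).coef_
    model = ElasticNet(
        alpha=lam, l1_ratio=alpha, fit_intercept=False, tol=1e-7, max_iter=10000
    )
    with np.errstate(all="ignore"):
        model.fit(X, y)
    return model.coef_


def elastic_net_solve(X, y, alpha: float, lam: float) -> np.ndarray:
    """Coefficients minimizing 1/2n ||y - Xb||^2 + lam (a|b|_1 + (1-a)|b|_2^2 / 2).

    ``alpha`` mixes lasso (1) and ridge (0); ``lam`` is the overall
    penalty.  lam = 0 returns ordinary least squares.  X must be
    feature-scaled (column sd 1 within tolerance).
    """
    X, y = _check_scaled(X, y)
    return _enet(X, y, alpha, lam)


def nested_cv_select(X, y, config: EnetConfig | None = None, seed=None) -> list[dict]:
    """One pass of nested 10-fold cross-validation over the full grid.

    For each outer fold the (alpha, lambda) pair minimizing mean inner-fold
    MSE is chosen, refit on the outer training set and used to predict the
    held-out subjects.  Returns one dict per outer fold with keys alpha,
    lam, coef, test_index, pred.
    """
    config = config or EnetConfig()
    X, y = _check_scaled(X, y)
    if np.var(y) == 0:
        raise ValueError("outcome has zero variance")
    rng_seed = config.seed if seed is None else seed
    outer = KFold(config.outer_folds, shuffle=True, random_state=rng_seed)
    lambdas = config.lambdas
    alphas = config.alphas
    results = []
    for fold_i, (tr, te) in enumerate(outer.split(X)):
        Xtr, ytr = X[tr], y[tr]
        inner = KFold(config.inner_folds, shuffle=True,
                      random_state=rng_seed * 1000 + fold_i)
        err = np.zeros((len(alphas), len(lambdas)))
        for itr, ite in inner.split(Xtr):
            Xi, yi = Xtr[itr], ytr[itr]
            Xv, yv = Xtr[ite], ytr[ite]
            for ai, a in enumerate(alphas):
                model = ElasticNet(alpha=lambdas[0], l1_ratio=a,
                                   fit_intercept=False, warm_start=True,
                                   tol=1e-4, max_iter=5000)
                for li, lam in enumerate(lambdas):
                    model.set_params(alpha=lam)
                    with np.errstate(all="ignore"):
                        model.fit(Xi, yi)
                    err[ai, li] += np.mean((yv - Xv @ model.coef_) ** 2)
        ai, li = np.unravel_index(np.argmin(err), err.shape)
        coef = _enet(Xtr, ytr - ytr.mean(), alphas[ai], lambdas[li])
        # no intercept: X and y enter globally scaled/centered, and a
        # per-fold intercept would leak the training-fold mean into the
        # held-out correlation
        results.append(
            {"alpha": alphas[ai], "lam": lambdas[li], "coef": coef,
             "test_index": te, "pred": X[te] @ coef}
        )
    return results


def _iteration_selection(folds: list[dict], n_items: int, aggregation: str) -> np.ndarray:
    nz = np.stack([f["coef"] != 0 for f in folds])
    if aggregation == "majority":
        return nz.sum(axis=0) > len(folds) / 2
    if aggregation == "all":
        return nz.all(axis=0)
    raise ValueError("aggregation must be 'majority' or 'all'")


def stability_retention(X, y, config: EnetConfig | None = None) -> StabilityResult:
    """Repeat nested CV over re-randomized splits; retain stable items.

    An item counts as selected in an iteration when its coefficient is
    nonzero in the majority of that iteration's outer-fold models (or in
    all of them with ``aggregation="all"``); items selected in at least
    ``retention_threshold`` of iterations are retained.  Also reports the
    out-of-fold prediction r (and p) per iteration and their medians.
    """
    config = config or EnetConfig()
    names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    counts = np.zeros(X.shape[1])
    rs, ps = [], []
    for it in range(config.n_iterations):
        folds = nested_cv_select(X, y, config, seed=config.seed + 7919 * it)
        counts += _iteration_selection(folds, X.shape[1], config.aggregation)
        pred = np.empty(len(y))
        for f in folds:
            pred[f["test_index"]] = f["pred"]
        if np.std(pred) > 0:
            r, p = pearsonr(pred, y)
        else:  # every fold returned the null model
            r, p = 0.0, 1.0
        rs.append(r)
        ps.append(p)
    freq = pd.Series(counts / config.n_iterations,
                     index=names if names is not None else np.arange(X.shape[1]))
    retained = list(freq.index[freq >= config.retention_threshold])
    return StabilityResult(
        retention_frequency=freq, retained=retained,
        cv_r=np.array(rs), cv_p=np.array(ps),
    )


def residualize(y, covariates: pd.DataFrame) -> np.ndarray:
    """Residuals of y on an intercept plus covariates (the outcome prep
    for item selection: the model-based index corrected for age, IQ and
    gender)."""
    Z = np.column_stack([np.ones(len(y)), np.asarray(covariates, dtype=float)])
    beta, *_ = np.linalg.lstsq(Z, np.asarray(y, dtype=float), rcond=None)
    return np.asarray(y) - Z @ beta


class StabilitySelector(BaseEstimator):
    """sklearn-style wrapper around :func:`stability_retention`.

    After ``fit(X, y)``: ``retention_frequency_``, ``retained_``,
    ``support_`` (boolean mask), ``cv_r_``, ``cv_p_``, ``median_r_``.
    """

    def __init__(self, config: EnetConfig | None = None):
        self.config = config

    def fit(self, X, y):
        cfg = self.config or EnetConfig()
        res = stability_retention(X, y, cfg)
        self.retention_frequency_ = res.retention_frequency
        self.retained_ = res.retained
        self.support_ = (res.retention_frequency >= cfg.retention_threshold).to_numpy()
        self.cv_r_ = res.cv_r
        self.cv_p_ = res.cv_p
        self.median_r_ = res.median_r
        self.median_p_ = res.median_p
        self.result_ = res
        return self
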