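"""Item-level trans-diagnostic factor pipeline.

Builds a heterogeneous correlation matrix over mixed-type questionnaire
items (Pearson between numeric items, polyserial between numeric and
binary, polychoric between binary), fits a maximum-likelihood factor
model to it, rotates obliquely (oblimin, gamma = 0), selects the number
of factors by the Cattell-Nelson-Gorsuch scree test (parallel analysis
available as a comparator), and produces regression-method factor scores
and per-questionnaire loading summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import ndtr
from scipy.stats import norm
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.multivariate.factor import Factor
from statsmodels.multivariate.factor_rotation._gpa_rotation import (
    GPA,
    oblimin_objective,
)

from ._bvn import bvn_cdf

HEYWOOD_FLOOR = 0.005


# ---------------------------------------------------------------------------
# mixed-type correlations


def _thresholds_from_margins(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Category values (sorted) and normal thresholds from sample margins."""
    vals, counts = np.unique(x, return_counts=True)
    cum = np.cumsum(counts)[:-1] / len(x)
    return vals, norm.ppf(cum)


def polychoric(x: np.ndarray, y: np.ndarray) -> float:
    """Two-step ML polychoric/tetrachoric correlation of two ordinal items.

    Thresholds are fixed at the values implied by the marginal
    distributions; the latent correlation is then estimated by maximizing
    the bivariate-normal cell likelihood.
    """
    xv, tx = _thresholds_from_margins(x)
    yv, ty = _thresholds_from_margins(y)
    if len(xv) < 2 or len(yv) < 2:
        raise ValueError("zero-variance item in polychoric correlation")
    xi = np.searchsorted(xv, x)
    yi = np.searchsorted(yv, y)
    table = np.zeros((len(xv), len(yv)))
    np.add.at(table, (xi, yi), 1.0)
    gx = np.concatenate([[-np.inf], tx, [np.inf]])
    gy = np.concatenate([[-np.inf], ty, [np.inf]])
    HX, HY = np.meshgrid(gx, gy, indexing="ij")

    def neg_ll(rho):
        C = bvn_cdf(HX, HY, rho)
        cells = C[1:, 1:] - C[:-1, 1:] - C[1:, :-1] + C[:-1, :-1]
        return -np.sum(table * np.log(np.clip(cells, 1e-12, None)))

    res = minimize_scalar(neg_ll, bounds=(-0.999, 0.999), method="bounded",
                          options={"xatol": 1e-6})
    return float(res.x)


def polyserial(x: np.ndarray, y: np.ndarray) -> float:
    """Two-step ML polyserial correlation (numeric x, ordinal/binary y)."""
    yv, ty = _thresholds_from_margins(y)
    if len(yv) < 2:
        raise ValueError("zero-variance item in polyserial correlation")
    if np.std(x) == 0:
        raise ValueError("zero-variance item in polyserial correlation")
    z = (x - x.mean()) / x.std(ddof=0)
    yi = np.searchsorted(yv, y)
    hi = np.concatenate([ty, [np.inf]])[yi]
    lo = np.concatenate([[-np.inf], ty])[yi]

    def neg_ll(rho):
        s = np.sqrt(1.0 - rho**2)
        p = ndtr((hi - rho * z) / s) - ndtr((lo - rho * z) / s)
        return -np.sum(np.log(np.clip(p, 1e-12, None)))

    res = minimize_scalar(neg_ll, bounds=(-0.999, 0.999), method="bounded",
                          options={"xatol": 1e-6})
    return float(res.x)


def nearest_psd(R: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Eigenvalue-clipped positive-semidefinite projection, unit diagonal."""
    w, V = np.linalg.eigh((R + R.T) / 2)
    R2 = (V * np.clip(w, eps, None)) @ V.T
    d = np.sqrt(np.diag(R2))
    return R2 / np.outer(d, d)


def heterogeneous_correlation(
    responses: pd.DataFrame, binary: dict | pd.Series | None = None
):
    """Mixed-type correlation matrix with per-pair method tags.

    ``binary`` marks which columns are binary (polychoric among
    themselves, polyserial against numeric columns); everything else is
    treated as numeric (Pearson).  Returns ``(R, tags, smoothed)`` where
    ``tags`` holds 'pearson'/'polyserial'/'polychoric' per pair.
    """
    cols = list(responses.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 items")
    X = responses.to_numpy(dtype=float)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [c for c, s in zip(cols, sd) if s == 0]
        raise ValueError(f"zero-variance items: {bad}")
    isbin = np.array(
        [bool(binary[c]) if binary is not None else False for c in cols]
    )
    p = len(cols)
    R = np.corrcoef(X, rowvar=False)  # Pearson base for numeric-numeric
    tags = np.full((p, p), "pearson", dtype=object)
    for i in range(p):
        for j in range(i + 1, p):
            if isbin[i] and isbin[j]:
                R[i, j] = R[j, i] = polychoric(X[:, i], X[:, j])
                tags[i, j] = tags[j, i] = "polychoric"
            elif isbin[i] != isbin[j]:
                num, cat = (j, i) if isbin[i] else (i, j)
                R[i, j] = R[j, i] = polyserial(X[:, num], X[:, cat])
                tags[i, j] = tags[j, i] = "polyserial"
    np.fill_diagonal(R, 1.0)
    smoothed = False
    w = np.linalg.eigvalsh((R + R.T) / 2)
    if w.min() < -1e-10:
        R = nearest_psd(R)
        smoothed = True
    Rdf = pd.DataFrame(R, index=cols, columns=cols)
    return Rdf, pd.DataFrame(tags, index=cols, columns=cols), smoothed


# ---------------------------------------------------------------------------
# factor extraction and rotation


@dataclass
class FactorSolution:
    """Unrotated + rotated ML factor solution on a correlation matrix."""

    loadings: np.ndarray            # unrotated, items x k
    pattern: np.ndarray             # oblimin pattern, items x k
    phi: np.ndarray                 # factor correlations, k x k
    uniqueness: np.ndarray
    eigenvalues: np.ndarray         # of the correlation matrix
    k: int
    items: list = field(default_factory=list)
    heywood: bool = False
    corr: np.ndarray | None = None

    @property
    def communalities(self) -> np.ndarray:
        return 1.0 - self.uniqueness

    def pattern_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.pattern, index=self.items,
            columns=[f"F{j+1}" for j in range(self.k)],
        )


def ml_factor_analysis(corr, k: int, nobs: int = 1000) -> FactorSolution:
    """Maximum-likelihood factor extraction on a correlation matrix.

    Heywood cases are handled by flooring uniquenesses at 0.005 and
    flagged on the returned solution.
    """
    items = list(corr.columns) if isinstance(corr, pd.DataFrame) else [
        f"item{i}" for i in range(np.asarray(corr).shape[0])
    ]
    R = np.asarray(corr, dtype=float)
    p = R.shape[0]
    if not 1 <= k < p:
        raise ValueError(f"k must satisfy 1 <= k < {p}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fa = Factor(corr=R, n_factor=k, method="ml", nobs=nobs)
        res = fa.fit()
    L = np.asarray(res.loadings)
    uniq = np.asarray(res.uniqueness)
    heywood = bool(np.any(uniq < HEYWOOD_FLOOR))
    if heywood:
        uniq = np.clip(uniq, HEYWOOD_FLOOR, None)
    eig = np.linalg.eigvalsh(R)[::-1]
    return FactorSolution(
        loadings=L, pattern=L.copy(), phi=np.eye(k), uniqueness=uniq,
        eigenvalues=eig, k=k, items=items, heywood=heywood, corr=R,
    )


def oblimin_rotate(loadings: np.ndarray, gamma: float = 0.0, tol: float = 1e-6):
    """Gradient-projection oblimin rotation.

    Returns ``(pattern, phi, trace)``; columns are sign-fixed so the
    largest-|loading| item of each factor loads positively.  For k = 1 the
    rotation is an identity passthrough.
    """
    L = np.asarray(loadings, dtype=float)
    if L.shape[1] < 2:
        return L.copy(), np.eye(L.shape[1]), np.array([])

    def vgQ(L=None, A=None, T=None):
        return oblimin_objective(L=L, A=A, T=T, gamma=gamma, rotation_method="oblique")

    Lr, phi, T, table = GPA(L, vgQ=vgQ, rotation_method="oblique", tol=tol)
    trace = np.asarray(table)[:, 1].astype(float)
    # sign convention
    for j in range(Lr.shape[1]):
        i = np.argmax(np.abs(Lr[:, j]))
        if Lr[i, j] < 0:
            Lr[:, j] *= -1
            phi[j, :] *= -1
            phi[:, j] *= -1
    return Lr, phi, trace


def rotate_solution(sol: FactorSolution, gamma: float = 0.0) -> FactorSolution:
    sol.pattern, sol.phi, _ = oblimin_rotate(sol.loadings, gamma=gamma)
    return sol


# ---------------------------------------------------------------------------
# factor-number selection


def cng_indicator(eigenvalues) -> int:
    """Cattell-Nelson-Gorsuch scree test.

    Least-squares slopes are fitted to each triple of adjacent
    eigenvalues; the retained dimensionality is the position (+2) where
    the difference between the slope of the following triple and the
    preceding triple is greatest.
    """
    e = np.asarray(eigenvalues, dtype=float)
    if len(e) < 6:
        raise ValueError("CNG needs at least 6 eigenvalues")
    t = np.arange(3, dtype=float)
    slope = lambda y: np.polyfit(t, y, 1)[0]
    diffs = [
        slope(e[i + 3 : i + 6]) - slope(e[i : i + 3])
        for i in range(len(e) - 5)
    ]
    # diffs[0] compares triples (e1,e2,e3) vs (e4,e5,e6): elbow after e3 -> k=3
    return int(np.argmax(diffs)) + 3


def parallel_analysis(
    responses: pd.DataFrame,
    n_reps: int = 500,
    quantile: float = 0.95,
    seed=None,
    corr: np.ndarray | None = None,
) -> int:
    """Horn's parallel analysis on permuted responses.

    k = number of observed eigenvalues exceeding the null quantile of the
    corresponding rank.  Observed eigenvalues come from ``corr`` if given,
    else the Pearson matrix of the responses.
    """
    rng = np.random.default_rng(seed)
    X = responses.to_numpy(dtype=float)
    n, p = X.shape
    obs = (
        np.sort(np.linalg.eigvalsh(np.asarray(corr)))[::-1]
        if corr is not None
        else np.sort(np.linalg.eigvalsh(np.corrcoef(X, rowvar=False)))[::-1]
    )
    null = np.empty((n_reps, p))
    for b in range(n_reps):
        Xp = np.column_stack([rng.permutation(X[:, j]) for j in range(p)])
        null[b] = np.sort(np.linalg.eigvalsh(np.corrcoef(Xp, rowvar=False)))[::-1]
    thresh = np.quantile(null, quantile, axis=0)
    above = obs > thresh
    k = 0
    while k < p and above[k]:
        k += 1
    return k


def select_n_factors(eigenvalues=None, method: str = "cng", **kw) -> int:
    if method == "cng":
        return cng_indicator(eigenvalues)
    if method == "parallel":
        return parallel_analysis(**kw)
    raise ValueError("method must be 'cng' or 'parallel'")


# ---------------------------------------------------------------------------
# scores and summaries


def factor_scores(
    sol: FactorSolution, responses: pd.DataFrame, method: str = "regression"
) -> pd.DataFrame:
    """Per-subject factor scores from the rotated solution (z-scored).

    Regression (Thurstone) scores use W = R^-1 (Lambda Phi); Bartlett
    scores weight by inverse uniquenesses.
    """
    X = responses[sol.items].to_numpy(dtype=float)
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    R = sol.corr if sol.corr is not None else np.corrcoef(X, rowvar=False)
    structure = sol.pattern @ sol.phi
    if method == "regression":
        try:
            W = np.linalg.solve(R, structure)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError("singular reproduced correlation matrix")
    elif method == "bartlett":
        U = 1.0 / np.clip(sol.uniqueness, HEYWOOD_FLOOR, None)
        L = sol.pattern
        M = (L.T * U) @ L
        W = (U[:, None] * L) @ np.linalg.inv(M)
    else:
        raise ValueError("method must be 'regression' or 'bartlett'")
    S = Z @ W
    S = (S - S.mean(axis=0)) / S.std(axis=0, ddof=0)
    return pd.DataFrame(
        S, index=responses.index, columns=[f"F{j+1}" for j in range(sol.k)]
    )


def loading_summary(
    sol: FactorSolution, questionnaires: pd.Series, threshold: float = 0.25
) -> pd.DataFrame:
    """Mean (SD) pattern loading per questionnaire per factor.

    ``questionnaires`` maps item id -> questionnaire tag.  Questionnaires
    whose mean loading strictly exceeds ``threshold`` on a factor are
    flagged as dominant for that factor.
    """
    pat = sol.pattern_frame()
    q = questionnaires.reindex(pat.index)
    rows = []
    for tag, grp in pat.groupby(q):
        row = {"questionnaire": tag}
        for f in pat.columns:
            row[f"{f}_mean"] = grp[f].mean()
            row[f"{f}_sd"] = grp[f].std(ddof=1) if len(grp) > 1 else 0.0
            row[f"{f}_dominant"] = grp[f].mean() > threshold
        rows.append(row)
    return pd.DataFrame(rows).set_index("questionnaire")


# ---------------------------------------------------------------------------
# estimator facade


class MixedFactorAnalysis(BaseEstimator, TransformerMixin):
    """Mixed-type correlation -> ML factor analysis -> oblimin pipeline.

    ``n_factors`` may be an integer or "cng" (scree-based selection).
    ``fit`` expects a responses DataFrame (subjects x items) and an
    optional ``binary`` mapping of item -> bool; ``transform`` returns
    regression-method factor scores.
    """

    def __init__(self, n_factors="cng", gamma: float = 0.0, nobs: int | None = None,
                 score_method: str = "regression"):
        self.n_factors = n_factors
        self.gamma = gamma
        self.nobs = nobs
        self.score_method = score_method

    def fit(self, responses: pd.DataFrame, binary=None):
        R, tags, smoothed = heterogeneous_correlation(responses, binary=binary)
        eig = np.sort(np.linalg.eigvalsh(R.to_numpy()))[::-1]
        k = (
            cng_indicator(eig)
            if isinstance(self.n_factors, str) and self.n_factors == "cng"
            else int(self.n_factors)
        )
        sol = ml_factor_analysis(R, k, nobs=self.nobs or len(responses))
        rotate_solution(sol, gamma=self.gamma)
        self.corr_ = R
        self.corr_method_tags_ = tags
        self.corr_smoothed_ = smoothed
        self.eigenvalues_ = eig
        self.k_ = k
        self.solution_ = sol
        self.loadings_ = sol.pattern_frame()
        self.phi_ = sol.phi
        return self

    def transform(self, responses: pd.DataFrame) -> pd.DataFrame:
        return factor_scores(self.solution_, responses, method=self.score_method)

    def loading_summary(self, questionnaires: pd.Series, threshold: float = 0.25):
        return loading_summary(self.solution_, questionnaires, threshold=threshold)
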