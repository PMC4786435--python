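"""One-trial-back stay regression: model-free and model-based indices.

The probability of repeating the previous first-stage choice ("stay") is
regressed on the previous trial's Reward (+1 rewarded / -1 unrewarded),
Transition (+1 common / -1 rare) and their interaction.  The Reward main
effect indexes model-free control; the Reward x Transition interaction
indexes model-based control.  Between-subject moderators (a symptom or
factor score, IQ, age, gender) enter interacted with all within-subject
terms; the Score x Reward x Transition coefficient measures how the
model-based index changes per SD of the score.

Two engines fit the group model:

``two_stage`` (default)
    Per-subject maximum-likelihood logistic coefficients (ridge-stabilized
    under separation) followed by OLS/WLS of each within-subject
    coefficient on the between-subject predictors.  Exactly calibrated
    stage-2 inference and fast enough for thousands of subjects.
``glmm``
    Penalized-likelihood generalized linear mixed model via the Laplace
    (posterior-mode) approximation, with random intercept, Reward,
    Transition and Reward x Transition per subject (diagonal covariance).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import norm
from sklearn.base import BaseEstimator

WITHIN_TERMS = ["Intercept", "Reward", "Transition", "Reward:Transition"]


# ---------------------------------------------------------------------------
# design construction


def build_stay_design(session, profile: dict | None = None) -> pd.DataFrame:
    """One row per valid consecutive trial pair of a session.

    Codings: stay 1 / switch 0 on first-stage choices; previous reward
    +1/-1; previous transition common +1 / rare -1.  The first trial
    yields no row and rows spanning a missed trial are dropped.
    """
    tr = session.trials
    prev = tr.shift(1)
    prev_missed = prev["missed"].to_numpy()
    prev_missed[0] = True
    valid = (~tr["missed"].to_numpy(dtype=bool)) & (~prev_missed.astype(bool))
    valid = pd.Series(valid, index=tr.index)
    if valid.sum() == 0:
        warnings.warn(f"session {session.subject_id}: no valid trial pairs")
    out = pd.DataFrame(
        {
            "subject_id": session.subject_id,
            "stay": (tr["c1"] == prev["c1"]).astype(int),
            "reward_prev": np.where(prev["reward"] == 1, 1, -1),
            "transition_prev": np.where(prev["transition"] == "common", 1, -1),
        }
    )[valid.to_numpy()]
    if profile:
        for k, v in profile.items():
            out[k] = v
    return out.reset_index(drop=True)


def build_designs(sessions, profiles: pd.DataFrame | None = None) -> pd.DataFrame:
    frames = [build_stay_design(s) for s in sessions]
    design = pd.concat(frames, ignore_index=True)
    if profiles is not None:
        design = design.merge(profiles.reset_index(), on="subject_id", how="left")
    return design


# ---------------------------------------------------------------------------
# per-subject logistic


def _irls(X, y, ridge=0.0, max_iter=100, tol=1e-10):
    """Newton/IRLS for (optionally ridge-penalized) logistic regression."""
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        grad = X.T @ (y - mu) - ridge * beta
        H = (X.T * w) @ X + ridge * np.eye(p)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    mu = expit(eta)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    H = (X.T * w) @ X + ridge * np.eye(p)
    cov = np.linalg.pinv(H)
    return beta, np.sqrt(np.diag(cov))


def fit_subject_logistic(design: pd.DataFrame, stabilize_ridge: float = 0.5):
    """ML logistic fit of stay on Reward, Transition and their interaction.

    Perfect (or quasi-) separation is detected by diverging coefficients
    and flagged; the returned coefficients are then ridge-stabilized with
    penalty ``stabilize_ridge``.
    """
    y = design["stay"].to_numpy(dtype=float)
    R = design["reward_prev"].to_numpy(dtype=float)
    T = design["transition_prev"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(R), R, T, R * T])
    if len(y) < 4:
        warnings.warn("fewer than 4 rows; coefficients are ridge-stabilized")
        beta, se = _irls(X, y, ridge=stabilize_ridge)
        separated = True
    else:
        beta, se = _irls(X, y, ridge=1e-8)
        separated = bool(np.any(np.abs(beta) > 10) or not np.all(np.isfinite(se)))
        if separated:
            beta, se = _irls(X, y, ridge=stabilize_ridge)
    return pd.Series(
        {
            "Intercept": beta[0],
            "Reward": beta[1],
            "Transition": beta[2],
            "Reward:Transition": beta[3],
            "se_Intercept": se[0],
            "se_Reward": se[1],
            "se_Transition": se[2],
            "se_Reward:Transition": se[3],
            "separated": separated,
        }
    )


def subject_coefficients(design: pd.DataFrame, **kw) -> pd.DataFrame:
    """Stay-regression coefficients for every subject in a long design."""
    return design.groupby("subject_id", sort=False).apply(
        lambda g: fit_subject_logistic(g, **kw), include_groups=False
    )


# ---------------------------------------------------------------------------
# group model


def _check_rank(B: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(B)
    if rank < B.shape[1]:
        # name columns whose removal restores full column rank
        bad = []
        for j in range(B.shape[1]):
            keep = [k for k in range(B.shape[1]) if k != j]
            if np.linalg.matrix_rank(B[:, keep]) == rank:
                bad.append(names[j])
        raise ValueError(f"rank-deficient between-subject design; collinear columns: {bad}")


class GroupStayModel(BaseEstimator):
    """Hierarchical stay regression with between-subject moderators.

    Parameters
    ----------
    score_cols : list of between-subject score columns (z-scored
        internally); may be empty for the covariates-only model.
    covariate_cols : continuous nuisance covariates, z-scored internally.
    gender_col : binary covariate entered as coded (-1 female / +1 male),
        not z-scored; None to omit.
    engine : "two_stage" (default) or "glmm".
    weighted : stage-2 WLS with inverse-variance weights from stage 1
        (two_stage engine only).

    After ``fit``: ``coef_table_`` (beta, se, z, p per term; within-subject
    terms carry the group-level effect, "<col>:<term>" rows the
    moderation), ``subject_coefs_``, ``subject_effects_`` (per-subject
    deviations from the between-subject predictions).
    """

    def __init__(
        self,
        score_cols=(),
        covariate_cols=("iq", "age"),
        gender_col="gender",
        engine="two_stage",
        weighted=False,
        quadratic_cols=(),
        stabilize_ridge=0.5,
    ):
        self.score_cols = score_cols
        self.covariate_cols = covariate_cols
        self.gender_col = gender_col
        self.engine = engine
        self.weighted = weighted
        self.quadratic_cols = quadratic_cols
        self.stabilize_ridge = stabilize_ridge

    def _between_design(self, subjects: pd.DataFrame):
        cols, names = [np.ones(len(subjects))], ["1"]
        for c in list(self.score_cols) + list(self.covariate_cols):
            x = subjects[c].to_numpy(dtype=float)
            sd = x.std(ddof=0)
            if sd == 0:
                raise ValueError(f"rank-deficient between-subject design; collinear columns: ['{c}']")
            cols.append((x - x.mean()) / sd)
            names.append(c)
        for c in self.quadratic_cols:
            x = subjects[c].to_numpy(dtype=float)
            z = (x - x.mean()) / x.std(ddof=0)
            cols.append(z**2 - (z**2).mean())
            names.append(f"{c}^2")
        if self.gender_col is not None:
            cols.append(subjects[self.gender_col].to_numpy(dtype=float))
            names.append(self.gender_col)
        B = np.column_stack(cols)
        _check_rank(B, names)
        return B, names

    def fit(self, design: pd.DataFrame, subjects: pd.DataFrame):
        """``design``: long stay design; ``subjects``: per-subject table
        indexed by subject_id carrying score/covariate columns."""
        subjects = subjects.loc[design["subject_id"].unique()]
        if self.engine == "two_stage":
            self._fit_two_stage(design, subjects)
        elif self.engine == "glmm":
            self._fit_glmm(design, subjects)
        else:
            raise ValueError("engine must be 'two_stage' or 'glmm'")
        return self

    def _fit_two_stage(self, design, subjects):
        coefs = subject_coefficients(design, stabilize_ridge=self.stabilize_ridge)
        coefs = coefs.loc[subjects.index]
        B, names = self._between_design(subjects)
        rows = []
        resid = {}
        for term in WITHIN_TERMS:
            y = coefs[term].to_numpy(dtype=float)
            if self.weighted:
                w = 1.0 / np.clip(coefs[f"se_{term}"].to_numpy(dtype=float) ** 2, 1e-6, None)
                res = sm.WLS(y, B, weights=w).fit()
            else:
                res = sm.OLS(y, B).fit()
            resid[term] = y - B @ res.params
            for name, b, se, t, p in zip(
                names, res.params, res.bse, res.tvalues, res.pvalues
            ):
                label = term if name == "1" else f"{name}:{term}"
                label = label.replace(":Intercept", "")
                rows.append({"term": label, "beta": b, "se": se, "z": t, "p": p})
        self.coef_table_ = pd.DataFrame(rows).set_index("term")
        self.subject_coefs_ = coefs
        self.subject_effects_ = pd.DataFrame(resid, index=coefs.index)
        self.n_subjects_ = len(subjects)
        return self

    def _fit_glmm(self, design, subjects):
        from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

        B, names = self._between_design(subjects)
        bmap = pd.DataFrame(B, columns=names, index=subjects.index)
        d = design.merge(
            bmap.reset_index().rename(columns={"index": "subject_id"}),
            on="subject_id", how="left",
        )
        R = d["reward_prev"].to_numpy(dtype=float)
        T = d["transition_prev"].to_numpy(dtype=float)
        within = {"Intercept": np.ones(len(d)), "Reward": R,
                  "Transition": T, "Reward:Transition": R * T}
        cols, labels = [], []
        for wname, wvec in within.items():
            for bname in names:
                cols.append(wvec * d[bname].to_numpy(dtype=float))
                lab = wname if bname == "1" else f"{bname}:{wname}"
                labels.append(lab.replace(":Intercept", ""))
        X = np.column_stack(cols)
        sub_codes, sub_idx = pd.factorize(d["subject_id"])
        n_sub = len(sub_idx)
        import scipy.sparse as sp

        blocks = []
        ident = []
        for k, wvec in enumerate(within.values()):
            m = sp.csr_matrix(
                (wvec, (np.arange(len(d)), sub_codes)), shape=(len(d), n_sub)
            )
            blocks.append(m)
            ident.extend([k] * n_sub)
        exog_vc = sp.hstack(blocks).tocsr()
        model = BinomialBayesMixedGLM(
            d["stay"].to_numpy(dtype=float), X, exog_vc, np.asarray(ident),
            fe_p=10.0,
        )
        fit = model.fit_map()
        se = np.sqrt(np.diag(fit.cov_params())[: X.shape[1]])
        beta = fit.fe_mean
        z = beta / se
        self.coef_table_ = pd.DataFrame(
            {"beta": beta, "se": se, "z": z, "p": 2 * norm.sf(np.abs(z))},
            index=pd.Index(labels, name="term"),
        )
        self.n_subjects_ = n_sub
        self._glmm_result_ = fit
        return self


def fit_group_model(design, subjects, score_cols=(), **kw) -> GroupStayModel:
    return GroupStayModel(score_cols=score_cols, **kw).fit(design, subjects)


def percent_change_index(fit, score: str | None = None) -> float:
    """Percent change in the model-based index per 1 SD of the score.

    Defined as 100 x (Score x Reward x Transition coefficient) divided by
    the group Reward x Transition coefficient; undefined when the group
    interaction is at zero.
    """
    table = fit.coef_table_ if isinstance(fit, GroupStayModel) else fit
    denom = table.loc["Reward:Transition", "beta"]
    if abs(denom) < 1e-8:
        raise ZeroDivisionError("group Reward:Transition coefficient is ~0; percent change undefined")
    if score is None:
        cands = [ix for ix in table.index if ix.endswith(":Reward:Transition")]
        if len(cands) != 1:
            raise ValueError(f"specify the score term; candidates: {cands}")
        score_term = cands[0]
    else:
        score_term = f"{score}:Reward:Transition"
    return float(100.0 * table.loc[score_term, "beta"] / denom)


def auxiliary_checks(
    design: pd.DataFrame,
    subjects: pd.DataFrame,
    score_col: str,
    covariate_cols=("iq", "age"),
    gender_col="gender",
    top_quantile: float = 0.75,
    min_subset: int = 30,
) -> dict:
    """Nonlinearity and severity-subset robustness checks.

    (a) refits the group model with an added squared score term;
    (b) refits on the top-25% ("putative patients") and bottom-75%
    subsets of the score.  Returns coefficient tables per analysis.
    """
    out = {}
    quad = GroupStayModel(
        score_cols=(score_col,), covariate_cols=covariate_cols,
        gender_col=gender_col, quadratic_cols=(score_col,),
    ).fit(design, subjects)
    out["quadratic"] = quad.coef_table_
    cut = subjects[score_col].quantile(top_quantile)
    for label, mask in (
        ("top25", subjects[score_col] > cut),
        ("bottom75", subjects[score_col] <= cut),
    ):
        ids = subjects.index[mask]
        if len(ids) < min_subset:
            warnings.warn(f"subset {label} below minimum size; skipped")
            continue
        sub_design = design[design["subject_id"].isin(ids)]
        m = GroupStayModel(
            score_cols=(score_col,), covariate_cols=covariate_cols,
            gender_col=gender_col,
        ).fit(sub_design, subjects.loc[ids])
        out[label] = m.coef_table_
    return out
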