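"""End-to-end study pipeline on synthetic populations.

Generate a population and its task behavior, apply the exclusion
cascade, estimate trans-diagnostic factors from the item battery, fit
the group stay regression with the compulsivity factor and covariates,
and convert the factor interaction into percent change in model-based
learning per SD.  Optional stages fit the full hybrid RL model by
hierarchical EM and run elastic-net stability selection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import qc as qc_mod
from . import stay as stay_mod
from .psych import MixedFactorAnalysis
from .synth import PopulationConfig, SubjectProfiles, generate_behavior, generate_population
from .task import TaskConfig, sessions_to_frame

FACTOR_ANCHORS = {
    "anxious_depression": "trait_anxiety",
    "compulsivity": "OCD",
    "social_withdrawal": "social_anxiety",
}


def label_factors(summary: pd.DataFrame) -> dict:
    """Label estimated factors by their dominant questionnaire.

    Mirrors the labeling convention: the factor with the highest mean
    loading from the anchor instrument gets the corresponding label.
    """
    mean_cols = [c for c in summary.columns if c.endswith("_mean")]
    labels = {}
    for label, anchor in FACTOR_ANCHORS.items():
        if anchor in summary.index:
            row = summary.loc[anchor, mean_cols]
            labels[label] = str(row.idxmax()).replace("_mean", "")
    return labels


def estimate_factors(profiles: SubjectProfiles, n_factors="cng"):
    """Factor-analyze the battery; returns (model, scores, labels)."""
    fa = MixedFactorAnalysis(n_factors=n_factors)
    fa.fit(profiles.responses, binary=profiles.battery.binary_map())
    scores = fa.transform(profiles.responses)
    summary = fa.loading_summary(profiles.battery.questionnaire_tags())
    labels = label_factors(summary)
    return fa, scores, labels


def run_study(
    config: PopulationConfig | None = None,
    task_config: TaskConfig | None = None,
    seed: int | None = None,
    n_factors="cng",
    score_source: str = "estimated",
    with_rl: bool = False,
    with_enet: bool = False,
    enet_config=None,
) -> dict:
    """Run the full synthetic study; returns a results dictionary.

    ``score_source`` picks the compulsivity moderator for the group
    regression: "estimated" uses factor scores recovered from the item
    battery (the full measurement chain); "true" uses the generator's
    latent factor-2 score, isolating the behavioral estimator chain from
    battery measurement error (calibration runs).
    """
    config = config or PopulationConfig()
    task_config = task_config or TaskConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    profiles = generate_population(config, seed=rng.integers(2**31))
    sessions = generate_behavior(profiles, task_config, seed=rng.integers(2**31))
    trials = sessions_to_frame(sessions)

    report = qc_mod.apply_exclusions(
        trials,
        catch_answers=profiles.catch_responses,
        iq_scores=profiles.subjects.reset_index()[["subject_id", "iq_n_correct"]]
        .rename(columns={"iq_n_correct": "n_correct"}),
    )
    kept = qc_mod.kept_subjects(report)
    kept_sessions = [s for s in sessions if s.subject_id in set(kept)]

    fa, scores, labels = estimate_factors(profiles, n_factors=n_factors)
    comp_col = labels.get("compulsivity", scores.columns[min(1, len(scores.columns) - 1)])

    subjects = profiles.subjects.loc[kept, ["age", "iq_hat", "gender"]].rename(
        columns={"iq_hat": "iq"}
    )
    if score_source == "true":
        subjects["factor2"] = profiles.subjects.loc[kept, "f2"]
    elif score_source == "estimated":
        subjects["factor2"] = scores.loc[kept, comp_col]
    else:
        raise ValueError("score_source must be 'estimated' or 'true'")
    design = stay_mod.build_designs(kept_sessions)
    model = stay_mod.GroupStayModel(score_cols=("factor2",)).fit(design, subjects)
    pct = stay_mod.percent_change_index(model, score="factor2")

    out = {
        "profiles": profiles,
        "sessions": sessions,
        "qc_report": report,
        "kept": kept,
        "factor_model": fa,
        "factor_scores": scores,
        "factor_labels": labels,
        "k_selected": fa.k_,
        "group_model": model,
        "coef_table": model.coef_table_,
        "percent_change_factor2": pct,
    }

    if with_rl:
        from .rl import HybridEM

        em = HybridEM(random_state=int(rng.integers(2**31))).fit(kept_sessions)
        out["rl_fit"] = em

    if with_enet:
        from .select import EnetConfig, StabilitySelector, residualize

        cfg = enet_config or EnetConfig(seed=int(rng.integers(2**31)))
        coefs = model.subject_coefs_
        yres = residualize(
            coefs["Reward:Transition"].to_numpy(),
            subjects[["age", "iq", "gender"]],
        )
        X = profiles.responses.loc[kept]
        Xz = (X - X.mean()) / X.std(ddof=0)
        sel = StabilitySelector(cfg).fit(Xz, yres)
        out["enet"] = sel

    return out
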