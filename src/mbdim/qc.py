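"""Sequential data-quality exclusions for task, questionnaire and IQ data.

Criteria fire in a fixed order, each applied to the subjects surviving the
previous one; a subject receives at most one exclusion reason (the first
to fire):

1. ``missed_trials`` -- missed more than 10% of task trials;
2. ``same_key``      -- pressed the same response key on more than 95% of
   trials on which a response was registered;
3. ``rt_outlier``    -- mean reaction time beyond 2 SD of the sample mean
   (two-sided by default; ``rt_rule="fast_only"`` flags only fast means);
4. ``catch_item``    -- wrong answer to the embedded attention-check item;
5. ``iq_zero``       -- zero correct answers on the adaptive IQ test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

REASONS = ("missed_trials", "same_key", "rt_outlier", "catch_item", "iq_zero")


@dataclass(frozen=True)
class ExclusionReport:
    subject_id: str
    excluded: bool
    reason: str  # one of REASONS or "none"
    order_applied: int  # 1-based index of the firing criterion, 0 if kept


def _per_subject_task_stats(trials: pd.DataFrame, rt_stat: str) -> pd.DataFrame:
    def stats(grp):
        n = len(grp)
        missed = grp["missed"].to_numpy(dtype=bool)
        responded = grp.loc[~missed]
        # keys pressed across both stages on responded trials
        keys = np.concatenate(
            [responded["c1"].to_numpy(), responded["c2"].to_numpy()]
        )
        if len(keys):
            same_key_frac = max(np.mean(keys == 0), np.mean(keys == 1))
        else:
            same_key_frac = 1.0
        rt = responded["rt"].to_numpy(dtype=float)
        rt = rt[np.isfinite(rt)]
        rt_summary = (
            (np.median(rt) if rt_stat == "median" else np.mean(rt))
            if len(rt)
            else np.nan
        )
        return pd.Series(
            {
                "miss_frac": missed.mean() if n else 1.0,
                "same_key_frac": same_key_frac,
                "rt_summary": rt_summary,
            }
        )

    return trials.groupby("subject_id").apply(stats, include_groups=False)


def apply_exclusions(
    trials: pd.DataFrame,
    catch_answers: pd.DataFrame | None = None,
    iq_scores: pd.DataFrame | None = None,
    miss_threshold: float = 0.10,
    same_key_threshold: float = 0.95,
    rt_sd: float = 2.0,
    rt_rule: str = "two_sided",
    rt_stat: str = "mean",
    rt_sample: str = "remaining",
) -> pd.DataFrame:
    """Apply the sequential exclusion cascade.

    Parameters
    ----------
    trials : long trial log with columns subject_id, c1, c2, missed, rt.
    catch_answers : columns subject_id, response, expected (catch passed
        iff response == expected); optional.
    iq_scores : columns subject_id, n_correct; optional.
    rt_sample : "remaining" computes the RT mean/SD over subjects who
        survived the earlier criteria (the sequential reading); "all" uses
        every subject.

    Returns a report DataFrame (subject_id, excluded, reason,
    order_applied) sorted by subject_id.
    """
    if trials.empty:
        raise ValueError("empty sample: exclusion statistics are undefined")
    if rt_rule not in ("two_sided", "fast_only"):
        raise ValueError("rt_rule must be 'two_sided' or 'fast_only'")
    if rt_stat not in ("mean", "median"):
        raise ValueError("rt_stat must be 'mean' or 'median'")

    stats = _per_subject_task_stats(trials, rt_stat)
    reason = pd.Series("none", index=stats.index, dtype=object)
    order = pd.Series(0, index=stats.index, dtype=int)

    hit = stats["miss_frac"] > miss_threshold
    reason[hit] = "missed_trials"
    order[hit] = 1

    alive = reason == "none"
    hit = alive & (stats["same_key_frac"] > same_key_threshold)
    reason[hit] = "same_key"
    order[hit] = 2

    alive = reason == "none"
    pool = stats.loc[alive if rt_sample == "remaining" else stats.index, "rt_summary"]
    pool = pool.dropna()
    if len(pool) >= 2:
        m, sd = pool.mean(), pool.std(ddof=1)
        low, high = m - rt_sd * sd, m + rt_sd * sd
        if rt_rule == "fast_only":
            out = stats["rt_summary"] < low
        else:
            out = (stats["rt_summary"] < low) | (stats["rt_summary"] > high)
        hit = alive & out.fillna(False)
        reason[hit] = "rt_outlier"
        order[hit] = 3

    if catch_answers is not None and len(catch_answers):
        ca = catch_answers.set_index("subject_id")
        failed = ca["response"] != ca["expected"]
        failed = failed.reindex(stats.index, fill_value=False)
        hit = (reason == "none") & failed
        reason[hit] = "catch_item"
        order[hit] = 4

    if iq_scores is not None and len(iq_scores):
        iq = iq_scores.set_index("subject_id")["n_correct"].reindex(stats.index)
        hit = (reason == "none") & (iq == 0)
        reason[hit] = "iq_zero"
        order[hit] = 5

    report = pd.DataFrame(
        {
            "subject_id": stats.index,
            "excluded": (reason != "none").to_numpy(),
            "reason": reason.to_numpy(),
            "order_applied": order.to_numpy(),
        }
    ).sort_values("subject_id", kind="stable").reset_index(drop=True)
    return report


def kept_subjects(report: pd.DataFrame) -> list:
    return report.loc[~report["excluded"], "subject_id"].tolist()
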