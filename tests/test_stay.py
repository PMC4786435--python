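"""Stay regression: design coding, subject fits, group model, indices."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_session
from _oracles import logistic_newton_reference

from mbdim.rl import HybridParams
from mbdim.stay import (
    GroupStayModel,
    auxiliary_checks,
    build_stay_design,
    build_designs,
    fit_subject_logistic,
    percent_change_index,
)
from mbdim.task import TaskConfig, simulate_session


class TestBuildDesign:
    def test_coding_rules_on_hand_listed_sequence(self):
        sess = make_session(
            [
                (0, "common", 0, 0, 1),
                (0, "rare", 1, 1, 0),
                (1, "common", 1, 0, 1),
                (1, "common", 1, 1, 0),
            ]
        )
        d = build_stay_design(sess)
        assert len(d) == 3
        # row 1: previous trial rewarded + common; stayed (0 -> 0)
        assert d.loc[0, ["stay", "reward_prev", "transition_prev"]].tolist() == [1, 1, 1]
        # row 2: previous unrewarded + rare; switched (0 -> 1)
        assert d.loc[1, ["stay", "reward_prev", "transition_prev"]].tolist() == [0, -1, -1]
        # row 3: previous rewarded + common; stayed (1 -> 1)
        assert d.loc[2, ["stay", "reward_prev", "transition_prev"]].tolist() == [1, 1, 1]

    def test_single_trial_session_yields_no_rows(self):
        sess = make_session([(0, "common", 0, 0, 1)])
        with pytest.warns(UserWarning):
            d = build_stay_design(sess)
        assert len(d) == 0

    def test_rows_spanning_missed_trials_dropped(self, default_params):
        sess = simulate_session(
            default_params, TaskConfig(n_trials=100), seed=1, miss_prob=0.2
        )
        d = build_stay_design(sess)
        missed = sess.trials["missed"].to_numpy()
        expected = np.sum(~missed[1:] & ~missed[:-1])
        assert len(d) == expected


class TestSubjectLogistic:
    def test_constructed_reward_dependence(self):
        rows = []
        for r in (1, -1):
            for t in (1, -1):
                stay = 1 if r == 1 else 0
                rows += [{"stay": stay, "reward_prev": r, "transition_prev": t}] * 25
        fit = fit_subject_logistic(pd.DataFrame(rows))
        assert fit["separated"]  # deterministic dependence separates
        assert fit["Reward"] > 1.0
        assert abs(fit["Reward:Transition"]) < 0.2

    def test_null_cells_give_zero_slopes(self):
        rows = []
        for r in (1, -1):
            for t in (1, -1):
                rows += [{"stay": 1, "reward_prev": r, "transition_prev": t}] * 10
                rows += [{"stay": 0, "reward_prev": r, "transition_prev": t}] * 10
        fit = fit_subject_logistic(pd.DataFrame(rows))
        for term in ("Intercept", "Reward", "Transition", "Reward:Transition"):
            assert fit[term] == pytest.approx(0.0, abs=1e-6)

    def test_matches_newton_raphson_oracle(self):
        rng = np.random.default_rng(8)
        R = rng.choice([-1, 1], 200)
        T = rng.choice([-1, 1], 200)
        eta = 0.3 + 0.5 * R + 0.1 * T + 0.4 * R * T
        y = (rng.random(200) < 1 / (1 + np.exp(-eta))).astype(int)
        d = pd.DataFrame({"stay": y, "reward_prev": R, "transition_prev": T})
        fit = fit_subject_logistic(d)
        X = np.column_stack([np.ones(200), R, T, R * T])
        oracle = logistic_newton_reference(X, y.astype(float))
        got = fit[["Intercept", "Reward", "Transition", "Reward:Transition"]].to_numpy()
        assert np.max(np.abs(got - oracle)) < 1e-6


def simulate_cohort(n_subjects, effect_pct=0.0, seed=0, n_trials=200):
    """Agents whose beta_MB declines linearly with a z-scored score."""
    rng = np.random.default_rng(seed)
    score = rng.standard_normal(n_subjects)
    cfg = TaskConfig(n_trials=n_trials)
    sessions, rows = [], []
    for i in range(n_subjects):
        bmb = max(0.01, 0.7 * (1 + effect_pct / 100 * score[i]) + rng.normal(0, 0.15))
        p = HybridParams(0.5, 1.2, bmb, 0.3, 0.5, 0.15)
        sessions.append(simulate_session(p, cfg, seed=rng, subject_id=f"s{i}"))
        rows.append(
            {"subject_id": f"s{i}", "score": score[i], "iq": rng.standard_normal(),
             "age": rng.normal(33, 11), "gender": rng.choice([-1, 1]), "beta_mb": bmb}
        )
    subjects = pd.DataFrame(rows).set_index("subject_id")
    return build_designs(sessions), subjects


class TestGroupModel:
    @pytest.fixture(scope="class")
    def planted(self):
        return simulate_cohort(250, effect_pct=-25.0, seed=5)

    def test_planted_negative_link_recovered(self, planted):
        design, subjects = planted
        m = GroupStayModel(score_cols=("score",)).fit(design, subjects)
        row = m.coef_table_.loc["score:Reward:Transition"]
        assert row["beta"] < 0
        assert row["p"] < 0.05
        assert m.coef_table_.loc["Reward:Transition", "beta"] > 0

    def test_affine_rescaling_of_covariate_leaves_fit_unchanged(self, planted):
        design, subjects = planted
        m1 = GroupStayModel(score_cols=("score",)).fit(design, subjects)
        subjects2 = subjects.copy()
        subjects2["age"] = subjects2["age"] * 12.0 + 100.0  # months, shifted
        m2 = GroupStayModel(score_cols=("score",)).fit(design, subjects2)
        pd.testing.assert_frame_equal(m1.coef_table_, m2.coef_table_)

    def test_collinear_covariates_named_in_error(self, planted):
        design, subjects = planted
        subjects2 = subjects.copy()
        subjects2["age_copy"] = subjects2["age"]
        with pytest.raises(ValueError, match="age"):
            GroupStayModel(
                score_cols=("score",), covariate_cols=("iq", "age", "age_copy")
            ).fit(design, subjects2)

    def test_pure_model_free_cohort_interaction_ci_covers_zero(self):
        rng = np.random.default_rng(9)
        cfg = TaskConfig(n_trials=200)
        sessions = [
            simulate_session(
                HybridParams(0.5, 1.2, 0.0, 0.3, 0.7, 0.15), cfg, seed=rng,
                subject_id=f"s{i}",
            )
            for i in range(120)
        ]
        subjects = pd.DataFrame(
            {"iq": rng.standard_normal(120), "age": rng.normal(33, 11, 120),
             "gender": rng.choice([-1, 1], 120)},
            index=pd.Index([f"s{i}" for i in range(120)], name="subject_id"),
        )
        m = GroupStayModel(score_cols=()).fit(build_designs(sessions), subjects)
        rew = m.coef_table_.loc["Reward"]
        inter = m.coef_table_.loc["Reward:Transition"]
        assert rew["beta"] > 2 * rew["se"]
        assert abs(inter["beta"]) < 1.96 * inter["se"]

    def test_glmm_and_two_stage_agree_on_sign_and_rough_magnitude(self):
        design, subjects = simulate_cohort(60, effect_pct=-30.0, seed=11, n_trials=150)
        two = GroupStayModel(score_cols=("score",)).fit(design, subjects)
        glmm = GroupStayModel(score_cols=("score",), engine="glmm").fit(design, subjects)
        for term in ("Reward", "Reward:Transition"):
            a = two.coef_table_.loc[term, "beta"]
            b = glmm.coef_table_.loc[term, "beta"]
            assert np.sign(a) == np.sign(b)
            assert abs(a - b) / abs(a) < 0.35


class TestPercentChange:
    def _table(self, score_beta, group_beta):
        return pd.DataFrame(
            {"beta": [group_beta, score_beta]},
            index=["Reward:Transition", "score:Reward:Transition"],
        )

    def test_consistency_with_reported_narrative_arithmetic(self):
        # a score interaction of -0.040 against a group interaction of
        # 0.286 corresponds to a ~14% reduction per SD
        assert percent_change_index(self._table(-0.040, 0.286), "score") == pytest.approx(
            -13.986, abs=0.01
        )

    def test_zero_score_interaction_gives_zero_percent(self):
        assert percent_change_index(self._table(0.0, 0.3), "score") == 0.0

    def test_scale_invariance_of_the_ratio(self):
        a = percent_change_index(self._table(-0.05, 0.25), "score")
        b = percent_change_index(self._table(-0.10, 0.50), "score")
        assert a == pytest.approx(b)

    def test_zero_group_interaction_is_undefined(self):
        with pytest.raises(ZeroDivisionError):
            percent_change_index(self._table(-0.05, 0.0), "score")


class TestAuxiliaryChecks:
    @pytest.fixture(scope="class")
    def linear_cohort(self):
        # large enough that the top-25% subset retains sign information
        return simulate_cohort(500, effect_pct=-30.0, seed=13)

    def test_quadratic_term_null_under_linear_generator(self, linear_cohort):
        design, subjects = linear_cohort
        out = auxiliary_checks(design, subjects, "score")
        quad = out["quadratic"]
        lin = quad.loc["score:Reward:Transition"]
        sq = quad.loc["score^2:Reward:Transition"]
        assert lin["beta"] < 0 and lin["p"] < 0.05
        assert abs(sq["beta"]) < 1.96 * sq["se"]

    def test_subset_slopes_share_sign(self, linear_cohort):
        design, subjects = linear_cohort
        out = auxiliary_checks(design, subjects, "score")
        top = out["top25"].loc["score:Reward:Transition", "beta"]
        bottom = out["bottom75"].loc["score:Reward:Transition", "beta"]
        assert np.sign(top) == np.sign(bottom) == -1

    def test_constant_score_raises_rank_error(self, linear_cohort):
        design, subjects = linear_cohort
        subjects2 = subjects.copy()
        subjects2["score"] = 1.0
        with pytest.raises(ValueError, match="score"):
            auxiliary_checks(design, subjects2, "score")

    def test_small_subset_skipped_with_warning(self, linear_cohort):
        design, subjects = linear_cohort
        with pytest.warns(UserWarning, match="top25"):
            out = auxiliary_checks(design, subjects, "score", min_subset=10_000)
        assert "top25" not in out


class TestMonotonicity:
    def test_subject_interaction_tracks_generative_beta_mb(self):
        from scipy.stats import spearmanr

        design, subjects = simulate_cohort(500, effect_pct=0.0, seed=17)
        m = GroupStayModel(score_cols=()).fit(design, subjects)
        coefs = m.subject_coefs_["Reward:Transition"].loc[subjects.index]
        rho, p = spearmanr(coefs, subjects["beta_mb"])
        assert rho > 0
        assert p < 1e-3


class TestPercentChangeProperties:
    from hypothesis import given, settings, strategies as st

    @given(
        score=st.floats(-0.5, 0.5),
        group=st.floats(0.05, 1.0),
        scale=st.floats(0.1, 10.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_ratio_invariant_under_common_rescaling(self, score, group, scale):
        t1 = pd.DataFrame(
            {"beta": [group, score]},
            index=["Reward:Transition", "score:Reward:Transition"],
        )
        t2 = pd.DataFrame(
            {"beta": [group * scale, score * scale]},
            index=["Reward:Transition", "score:Reward:Transition"],
        )
        a = percent_change_index(t1, "score")
        b = percent_change_index(t2, "score")
        assert a == pytest.approx(b, rel=1e-9, abs=1e-9)
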