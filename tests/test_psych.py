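"""Mixed-type correlations, factor extraction, rotation, selection, scores."""

import numpy as np
import pandas as pd
import pytest

from _oracles import tetrachoric_grid_reference

from mbdim.psych import (
    MixedFactorAnalysis,
    cng_indicator,
    factor_scores,
    heterogeneous_correlation,
    loading_summary,
    ml_factor_analysis,
    oblimin_rotate,
    parallel_analysis,
    polychoric,
    polyserial,
    rotate_solution,
    select_n_factors,
)


class TestPolychoric:
    def test_recovers_latent_correlation_from_dichotomized_normal(self):
        rng = np.random.default_rng(0)
        n = 50_000
        z1 = rng.standard_normal(n)
        z2 = 0.5 * z1 + np.sqrt(1 - 0.25) * rng.standard_normal(n)
        rho = polychoric((z1 > 0).astype(int), (z2 > 0).astype(int))
        assert rho == pytest.approx(0.5, abs=0.02)

    def test_matches_grid_search_ml_oracle_on_2x2_table(self):
        rng = np.random.default_rng(1)
        for true_rho, cut1, cut2 in [(0.4, 0.0, 0.3), (-0.6, -0.5, 0.2), (0.0, 0.0, 0.0)]:
            n = 4000
            z1 = rng.standard_normal(n)
            z2 = true_rho * z1 + np.sqrt(1 - true_rho**2) * rng.standard_normal(n)
            x = (z1 > cut1).astype(int)
            y = (z2 > cut2).astype(int)
            table = np.zeros((2, 2))
            np.add.at(table, (x, y), 1)
            got = polychoric(x, y)
            oracle = tetrachoric_grid_reference(table)
            assert got == pytest.approx(oracle, abs=0.01)

    def test_polyserial_recovers_latent_correlation(self):
        rng = np.random.default_rng(2)
        n = 20_000
        x = rng.standard_normal(n)
        z = 0.6 * x + 0.8 * rng.standard_normal(n)
        y = np.digitize(z, [-1.0, 0.0, 1.0])
        assert polyserial(x, y) == pytest.approx(0.6, abs=0.02)

    def test_zero_variance_item_rejected(self):
        with pytest.raises(ValueError):
            polychoric(np.zeros(100, int), np.arange(100) % 2)


class TestHeterogeneousCorrelation:
    def test_all_numeric_equals_pearson_exactly(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(200, 5)), columns=list("abcde"))
        R, tags, smoothed = heterogeneous_correlation(df)
        assert np.allclose(R.to_numpy(), np.corrcoef(df.to_numpy(), rowvar=False))
        assert (tags.to_numpy() == "pearson").all()
        assert not smoothed

    def test_diagonal_is_one_and_tags_assigned_per_pair(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            {
                "num1": rng.normal(size=500),
                "num2": rng.normal(size=500),
                "bin1": rng.integers(0, 2, 500),
                "bin2": rng.integers(0, 2, 500),
            }
        )
        R, tags, _ = heterogeneous_correlation(df, binary={"num1": False, "num2": False, "bin1": True, "bin2": True})
        assert np.allclose(np.diag(R), 1.0)
        assert tags.loc["num1", "num2"] == "pearson"
        assert tags.loc["num1", "bin1"] == "polyserial"
        assert tags.loc["bin1", "bin2"] == "polychoric"

    def test_zero_variance_item_named_in_error(self):
        df = pd.DataFrame({"good": np.random.default_rng(5).normal(size=50), "flat": 1.0})
        with pytest.raises(ValueError, match="flat"):
            heterogeneous_correlation(df)

    def test_fewer_than_two_items_rejected(self):
        with pytest.raises(ValueError):
            heterogeneous_correlation(pd.DataFrame({"only": np.arange(10.0)}))


class TestMLFactorAnalysis:
    def test_rank_one_structure_recovers_uniform_loading(self):
        lam = 0.8
        p = 8
        R = np.full((p, p), lam * lam)
        np.fill_diagonal(R, 1.0)
        sol = ml_factor_analysis(pd.DataFrame(R), k=1)
        L = np.abs(sol.loadings[:, 0])
        assert np.allclose(L, lam, atol=1e-3)

    @pytest.mark.parametrize("k", [0, 20])
    def test_out_of_range_k_rejected(self, k):
        R = np.eye(6)
        with pytest.raises(ValueError):
            ml_factor_analysis(pd.DataFrame(R), k=k)

    def test_reproduced_correlation_error_decreases_in_k(self):
        rng = np.random.default_rng(6)
        L = rng.uniform(0.2, 0.7, (15, 3)) * (rng.random((15, 3)) < 0.6)
        R = L @ L.T
        np.fill_diagonal(R, 1.0)
        Rdf = pd.DataFrame(R)
        rmsr = []
        for k in (1, 2, 3):
            sol = ml_factor_analysis(Rdf, k=k)
            fitted = sol.loadings @ sol.loadings.T + np.diag(sol.uniqueness)
            off = ~np.eye(15, dtype=bool)
            rmsr.append(np.sqrt(np.mean((R - fitted)[off] ** 2)))
        assert rmsr[0] > rmsr[1] > rmsr[2]


class TestOblimin:
    def _toy_loadings(self, seed=7):
        rng = np.random.default_rng(seed)
        L = np.zeros((20, 3))
        L[:7, 0] = rng.uniform(0.5, 0.8, 7)
        L[7:14, 1] = rng.uniform(0.5, 0.8, 7)
        L[14:, 2] = rng.uniform(0.5, 0.8, 6)
        return L

    def test_simple_structure_is_a_fixed_point(self):
        L = self._toy_loadings()
        Lr, phi, _ = oblimin_rotate(L)
        # same column space, near-identity rotation up to permutation/sign
        perm = np.abs(Lr.T @ L)
        assert np.allclose(np.sort(perm.max(axis=0)), np.sort(np.diag(L.T @ L)), atol=1e-2)
        assert np.allclose(np.abs(Lr).max(axis=1), np.abs(L).max(axis=1), atol=1e-6)

    def test_rotation_preserves_fitted_correlation(self):
        rng = np.random.default_rng(8)
        A = self._toy_loadings() + rng.normal(0, 0.1, (20, 3))
        Lr, phi, _ = oblimin_rotate(A)
        assert np.allclose(Lr @ phi @ Lr.T, A @ A.T, atol=1e-8)

    def test_criterion_nonincreasing_along_iterations(self):
        rng = np.random.default_rng(9)
        A = rng.normal(size=(20, 3))
        _, _, trace = oblimin_rotate(A)
        assert np.all(np.diff(trace) <= 1e-10)

    def test_k_equals_one_passthrough(self):
        L = np.abs(np.random.default_rng(10).normal(size=(10, 1)))
        Lr, phi, trace = oblimin_rotate(L)
        assert np.array_equal(Lr, L)
        assert phi.shape == (1, 1)

    def test_sign_convention_largest_loading_positive(self):
        L = -self._toy_loadings()
        Lr, _, _ = oblimin_rotate(L)
        for j in range(Lr.shape[1]):
            assert Lr[np.argmax(np.abs(Lr[:, j])), j] > 0


class TestFactorNumberSelection:
    def test_constructed_elbow_returns_three(self):
        eig = np.r_[10.0, 6.0, 3.0, 1.0 - 0.05 * np.arange(20)]
        assert cng_indicator(eig) == 3

    def test_too_few_eigenvalues_rejected(self):
        with pytest.raises(ValueError):
            cng_indicator([3.0, 2.0, 1.0, 0.5, 0.2])

    def test_pure_noise_battery_parallel_analysis_returns_zero(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(rng.normal(size=(300, 15)))
        k = parallel_analysis(df, n_reps=200, seed=0)
        assert k <= 1  # no real structure above the null band

    def test_select_dispatches(self):
        eig = np.r_[10.0, 6.0, 3.0, 1.0 - 0.05 * np.arange(20)]
        assert select_n_factors(eig, method="cng") == 3
        with pytest.raises(ValueError):
            select_n_factors(eig, method="nope")


class TestFactorScores:
    def _fit_toy(self, seed=12):
        rng = np.random.default_rng(seed)
        F = rng.standard_normal((2000, 2))
        L = np.zeros((12, 2))
        L[:6, 0] = 0.7
        L[6:, 1] = 0.7
        X = F @ L.T + rng.standard_normal((2000, 12)) * np.sqrt(1 - 0.49)
        df = pd.DataFrame(X, columns=[f"i{j}" for j in range(12)])
        fa = MixedFactorAnalysis(n_factors=2).fit(df)
        return fa, df, F

    def test_subject_at_item_means_scores_zero(self):
        fa, df, _ = self._fit_toy()
        probe = pd.DataFrame([df.mean()], index=["avg"])
        full = pd.concat([df, probe])
        s = factor_scores(fa.solution_, full)
        assert np.allclose(s.loc["avg"].to_numpy(), 0.0, atol=0.05)

    def test_scores_recover_generating_factors(self):
        fa, df, F = self._fit_toy()
        s = fa.transform(df).to_numpy()
        cors = np.abs(np.corrcoef(s.T, F.T)[:2, 2:])
        assert np.sort(cors.max(axis=1))[0] > 0.8

    def test_disjoint_blocks_scores_depend_on_own_block(self):
        fa, df, _ = self._fit_toy()
        s0 = fa.transform(df)
        bumped = df.copy()
        bumped.iloc[:, :6] += 1.0  # shift only block 1 items
        s1 = factor_scores(fa.solution_, pd.concat([df, bumped]))
        # identify the factor aligned with block 1
        j = int(np.argmax(np.abs(fa.solution_.pattern[0])))
        other = 1 - j
        delta = s1.iloc[len(df):].to_numpy() - s1.iloc[: len(df)].to_numpy()
        assert np.abs(delta[:, j]).mean() > 5 * np.abs(delta[:, other]).mean()


class TestLoadingSummary:
    def _solution_with_pattern(self, pattern, items):
        from mbdim.psych import FactorSolution

        k = pattern.shape[1]
        return FactorSolution(
            loadings=pattern.copy(), pattern=pattern, phi=np.eye(k),
            uniqueness=np.ones(len(items)) * 0.5,
            eigenvalues=np.ones(len(items)), k=k, items=items,
        )

    def test_uniform_block_flagged_dominant(self):
        items = [f"q2_{i}" for i in range(5)]
        pattern = np.column_stack([np.zeros(5), np.full(5, 0.5)])
        sol = self._solution_with_pattern(pattern, items)
        tags = pd.Series(["Q2"] * 5, index=items)
        tab = loading_summary(sol, tags)
        assert tab.loc["Q2", "F2_mean"] == pytest.approx(0.5)
        assert tab.loc["Q2", "F2_sd"] == pytest.approx(0.0)
        assert bool(tab.loc["Q2", "F2_dominant"])

    def test_threshold_is_strict_at_quarter(self):
        items = [f"q_{i}" for i in range(4)]
        pattern = np.full((4, 1), 0.24)
        sol = self._solution_with_pattern(pattern, items)
        tab = loading_summary(sol, pd.Series(["Q"] * 4, index=items))
        assert not bool(tab.loc["Q", "F1_dominant"])

    def test_two_questionnaire_toy_matches_hand_computation(self):
        items = ["a1", "a2", "b1", "b2"]
        pattern = np.array([[0.6, 0.0], [0.4, 0.1], [0.0, 0.3], [0.1, 0.5]])
        sol = self._solution_with_pattern(pattern, items)
        tags = pd.Series(["A", "A", "B", "B"], index=items)
        tab = loading_summary(sol, tags)
        assert tab.loc["A", "F1_mean"] == pytest.approx(0.5)
        assert tab.loc["A", "F1_sd"] == pytest.approx(np.std([0.6, 0.4], ddof=1))
        assert tab.loc["B", "F2_mean"] == pytest.approx(0.4)
        assert bool(tab.loc["B", "F2_dominant"])


class TestRecovery:
    def test_three_factor_battery_congruence_after_rotation(self):
        # moderately sized generative check; the full-battery version runs
        # in the acceptance suite
        from mbdim.synth import PopulationConfig, generate_population

        cfg = PopulationConfig(n_subjects=900, item_scale=0.3, seed=21)
        prof = generate_population(cfg, seed=2)
        fa = MixedFactorAnalysis(n_factors=3).fit(
            prof.responses, binary=prof.battery.binary_map()
        )
        lam_true = prof.battery.analysis_items[["lam1", "lam2", "lam3"]].to_numpy()
        lam_est = fa.solution_.pattern
        # Tucker congruence, best assignment per true factor
        c = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                c[i, j] = abs(lam_true[:, i] @ lam_est[:, j]) / np.sqrt(
                    (lam_true[:, i] ** 2).sum() * (lam_est[:, j] ** 2).sum()
                )
        assert np.sort(c.max(axis=1)).min() > 0.9
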