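import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ergosc.explain import (
    coarse_disease_groups,
    compact_letters,
    games_howell,
    pearson_correlation,
    run_lda,
    run_pca,
    select_high_cov,
    so_score,
    so_score_from_pca,
    welch_anova,
)


class TestSelectHighCov:
    def test_cov_not_variance_ranks(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "big_mean": 100.0 + 10.0 * rng.standard_normal(500),
            "small_mean": 10.0 + 5.0 * rng.standard_normal(500),
        })
        assert select_high_cov(df, 2) == ["small_mean", "big_mean"]

    def test_constant_ranks_last(self):
        df = pd.DataFrame({"c": np.full(50, 7.0),
                           "v": np.random.default_rng(1).random(50) + 1})
        assert select_high_cov(df, 2) == ["v", "c"]

    def test_k_larger_than_variable_count(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 5.0]})
        assert len(select_high_cov(df, 10)) == 2

    def test_zero_mean_excluded_with_warning(self):
        df = pd.DataFrame({"z": [-1.0, 1.0], "a": [1.0, 2.0]})
        with pytest.warns(UserWarning):
            assert select_high_cov(df, 5) == ["a"]


class TestPCA:
    def test_diagonal_data(self):
        rng = np.random.default_rng(0)
        t = rng.standard_normal(200)
        df = pd.DataFrame({"x": t, "y": t + 1e-6 * rng.standard_normal(200)})
        res = run_pca(df, ["x", "y"])
        assert np.allclose(np.abs(res.loadings[:, 0]), 1 / np.sqrt(2), atol=1e-3)
        assert res.variance_fraction[0] > 0.999

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.standard_normal((50, 6)), columns=list("abcdef"))
        res = run_pca(df, list("abcdef"))
        assert np.allclose(res.loadings.T @ res.loadings, np.eye(6), atol=1e-9)

    def test_reconstruction_from_all_components(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.standard_normal((40, 5)), columns=list("abcde"))
        res = run_pca(df, list("abcde"))
        Z = (df.to_numpy() - res.mean) / res.scale
        assert np.allclose(res.scores @ res.loadings.T, Z, atol=1e-8)

    def test_contributions_sum_to_one_per_component(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.standard_normal((30, 4)), columns=list("abcd"))
        res = run_pca(df, list("abcd"))
        assert np.allclose(res.contributions.sum(axis=0), 1.0)

    def test_two_factor_model_variance_share(self):
        # oracle: eigenvalues of the exact population covariance
        rng = np.random.default_rng(4)
        p, n = 20, 4000
        W = rng.standard_normal((2, p))
        noise_sd = 0.6
        F = rng.standard_normal((n, 2))
        X = F @ W + noise_sd * rng.standard_normal((n, p))
        cols = [f"v{i}" for i in range(p)]
        df = pd.DataFrame(X, columns=cols)
        res = run_pca(df, cols, standardize=False)
        cov = W.T @ W + noise_sd**2 * np.eye(p)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        expected = eig[:2].sum() / eig.sum()
        assert res.variance_fraction[:2].sum() == pytest.approx(expected, abs=0.05)

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError):
            run_pca(pd.DataFrame({"a": [1.0], "b": [2.0]}), ["a", "b"])


class TestSOScore:
    def test_unit_loading_returns_variable(self):
        df = pd.DataFrame({"x1": [1.0, 2.0, 3.0], "x2": [9.0, 9.0, 9.0]})
        s = so_score(df, {"x1": 1.0, "x2": 0.0})
        assert np.allclose(s, df["x1"])

    def test_zero_loadings_zero_score(self):
        df = pd.DataFrame({"x1": [1.0, 2.0]})
        assert np.allclose(so_score(df, {"x1": 0.0}), 0.0)

    def test_linearity(self):
        df = pd.DataFrame({"a": [1.0, 4.0], "b": [2.0, -1.0]})
        w = {"a": 0.3, "b": -0.7}
        assert np.allclose(so_score(2 * df, w), 2 * so_score(df, w))

    def test_name_mismatch_rejected(self):
        with pytest.raises(ValueError, match="nope"):
            so_score(pd.DataFrame({"a": [1.0]}), {"nope": 1.0})

    def test_consistency_with_pc1_scores(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.standard_normal((60, 4)), columns=list("abcd"))
        res = run_pca(df, list("abcd"))
        s = so_score_from_pca(df, res)
        assert np.allclose(s.to_numpy(), res.scores[:, 0], atol=1e-9)


class TestPearson:
    def test_identity(self):
        x = np.arange(10.0)
        r, _ = pearson_correlation(x, x)
        assert r == pytest.approx(1.0)

    def test_negative_affine(self):
        x = np.arange(10.0)
        r, _ = pearson_correlation(x, -2 * x + 3)
        assert r == pytest.approx(-1.0)

    def test_null_rejection_rate(self):
        # critical |r| for n=100 at alpha=0.05 is 0.197
        rng = np.random.default_rng(6)
        hits = sum(
            abs(pearson_correlation(rng.standard_normal(100),
                                    rng.standard_normal(100))[0]) < 0.197
            for _ in range(1000)
        )
        assert 0.92 <= hits / 1000 <= 0.975

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError):
            pearson_correlation(np.ones(10), np.arange(10.0))


class TestLDA:
    def test_well_separated_gaussians(self):
        rng = np.random.default_rng(7)
        a = rng.standard_normal((150, 3))
        b = rng.standard_normal((150, 3)) + np.array([6.0, 0.0, 0.0])
        df = pd.DataFrame(np.vstack([a, b]), columns=["x", "y", "z"])
        df["group"] = ["a"] * 150 + ["b"] * 150
        res = run_lda(df, ["x", "y", "z"])
        assert all(r >= 0.99 for r in res.recall.values())
        assert res.axes.shape[1] <= 1

    def test_identical_distributions_chance_recall(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.standard_normal((200, 3)), columns=["x", "y", "z"])
        df["group"] = ["a", "b"] * 100
        res = run_lda(df, ["x", "y", "z"], validation="loo")
        assert 0.3 <= np.mean(list(res.recall.values())) <= 0.7

    def test_single_group_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "group": ["a", "a"]})
        with pytest.raises(ValueError):
            run_lda(df, ["x"])

    def test_coarse_grouping(self):
        labels = ["control", "overweight", "obesity", "mets", "dm_no_dr"]
        assert coarse_disease_groups(labels) == [
            "control", "risk_factors", "risk_factors", "risk_factors", "diabetes"
        ]


class TestWelchANOVA:
    def test_two_group_equals_welch_t_squared(self):
        rng = np.random.default_rng(9)
        a = rng.standard_normal(12) * 2 + 1
        b = rng.standard_normal(20) * 5
        res = welch_anova([a, b])
        t, p = sps.ttest_ind(a, b, equal_var=False)
        assert res.F == pytest.approx(t**2, abs=1e-9)
        assert res.p == pytest.approx(p, abs=1e-9)

    def test_equal_groups_f_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = welch_anova([x, x.copy()])
        assert res.F == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_matches_pingouin(self):
        rng = np.random.default_rng(10)
        groups = [rng.standard_normal(n) * s + m
                  for n, s, m in [(10, 1, 0), (15, 3, 1), (12, 2, -1)]]
        res = welch_anova(groups)
        import pingouin as pg

        data = pd.DataFrame(
            [(i, v) for i, g in enumerate(groups) for v in g], columns=["g", "v"]
        )
        ref = pg.welch_anova(data=data, dv="v", between="g")
        assert res.F == pytest.approx(float(ref["F"][0]), rel=1e-9)
        assert res.p == pytest.approx(float(ref["p_unc"][0]), rel=1e-6)

    def test_reduces_to_classical_anova_under_equal_variance(self):
        rng = np.random.default_rng(11)
        groups = [rng.standard_normal(500) for _ in range(3)]
        # force exactly equal group variances, then separate the means
        groups = [(g - g.mean()) / g.std(ddof=1) + m
                  for g, m in zip(groups, (0.0, 0.2, 0.4))]
        res = welch_anova(groups)
        classic = sps.f_oneway(*groups)
        assert res.F == pytest.approx(classic.statistic, rel=0.01)

    def test_zero_variance_group_rejected(self):
        with pytest.raises(ValueError):
            welch_anova([np.ones(5), np.arange(5.0)])


def test_games_howell_pairs_and_letters():
    rng = np.random.default_rng(12)
    samples = {
        "a": rng.standard_normal(30),
        "b": rng.standard_normal(30) + 5.0,
        "c": rng.standard_normal(30) + 5.1,
    }
    table = games_howell(samples)
    assert len(table) == 3  # all pairs
    sig = {
        (row["A"], row["B"])
        for _, row in table.iterrows()
        if row["pval"] < 0.05
    }
    letters = compact_letters(["a", "b", "c"], sig)
    assert letters["a"] != letters["b"]  # separated groups share no letter
    assert set(letters["b"]) & set(letters["c"])  # close groups share one
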