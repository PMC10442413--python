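import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sst

from crowdeda.stats import (MixedModelSpec, RmMatrix, analyze_study,
                            cohens_d, friedman, gg_epsilon, ks_normality,
                            mixed_mediation, posthoc_t_bonferroni,
                            rm_anova_gg)


def _matrix(values, labels=None):
    values = np.asarray(values, float)
    labels = labels or [f"c{i}" for i in range(values.shape[1])]
    subjects = [f"s{i}" for i in range(values.shape[0])]
    return RmMatrix(values=values, labels=labels, subjects=subjects)


class TestKsNormality:
    def test_statistic_in_unit_interval(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            d, p = ks_normality(rng.standard_normal(40))
            assert 0.0 <= d <= 1.0
            assert 0.0 <= p <= 1.0

    def test_normal_samples_rarely_rejected(self):
        rng = np.random.default_rng(1)
        kept = sum(ks_normality(rng.standard_normal(1000))[1] > 0.05
                   for _ in range(100))
        assert kept >= 90

    def test_exponential_samples_rejected(self):
        rng = np.random.default_rng(2)
        rejected = sum(ks_normality(rng.exponential(1.0, 1000))[1] < 0.05
                       for _ in range(100))
        assert rejected >= 95

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_normality(np.full(10, 3.0))

    def test_agrees_with_statsmodels_lilliefors_statistic(self):
        from statsmodels.stats.diagnostic import lilliefors

        rng = np.random.default_rng(3)
        x = rng.standard_normal(200)
        d_ours, _ = ks_normality(x)
        d_ref, _ = lilliefors(x, dist="norm")
        assert d_ours == pytest.approx(d_ref, abs=1e-10)


def _exact_friedman_p(values):
    """Independent brute-force oracle: enumerate all within-row rank
    permutations and count those with a statistic >= the observed one."""
    ranks = np.apply_along_axis(sst.rankdata, 1, np.asarray(values, float))
    n, k = ranks.shape

    def q_of(r):
        rj = r.sum(axis=0)
        return 12.0 / (n * k * (k + 1)) * (rj @ rj) - 3.0 * n * (k + 1)

    q_obs = q_of(ranks)
    perms = list(itertools.permutations(range(k)))
    hits = total = 0
    for combo in itertools.product(perms, repeat=n):
        r = np.vstack([ranks[i, list(p)] for i, p in enumerate(combo)])
        total += 1
        if q_of(r) >= q_obs - 1e-9:
            hits += 1
    return hits / total


class TestFriedman:
    def test_identical_rows_give_zero_statistic(self):
        m = _matrix(np.tile([2.0, 2.0, 2.0], (5, 1)))
        rep = friedman(m)
        assert rep.statistic == 0.0
        assert rep.p == 1.0

    @pytest.mark.filterwarnings("ignore:zero-variance")
    def test_perfectly_ordered_rows_give_q_30(self):
        """n=10 subjects, k=4 strictly increasing rows: ranks are 1..4 in
        every row, so Q = 12/200 * 3000 - 150 = 30."""
        base = np.arange(4, dtype=float)
        m = _matrix(np.vstack([base + i for i in range(10)]))
        rep = friedman(m, p_method="chi2")
        assert rep.statistic == pytest.approx(30.0)
        assert rep.df1 == 3
        assert rep.p == pytest.approx(float(sst.chi2.sf(30.0, 3)))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_small_table_p_matches_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.standard_normal((4, 3))
        rep = friedman(_matrix(values))
        assert rep.test == "friedman[exact]"
        assert rep.p == pytest.approx(_exact_friedman_p(values), abs=0.01)

    def test_invariant_under_monotone_row_transforms(self):
        rng = np.random.default_rng(5)
        values = rng.standard_normal((6, 3))
        transformed = values.copy()
        transformed[2] = np.exp(values[2])      # strictly monotone per row
        transformed[4] = 3 * values[4] + 1
        a = friedman(_matrix(values))
        b = friedman(_matrix(transformed))
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p == pytest.approx(b.p)

    def test_matches_scipy_on_untied_data(self):
        rng = np.random.default_rng(8)
        values = rng.standard_normal((12, 4))
        rep = friedman(_matrix(values), p_method="chi2")
        ref = sst.friedmanchisquare(*values.T)
        assert rep.statistic == pytest.approx(ref.statistic)
        assert rep.p == pytest.approx(ref.pvalue)


class TestRmAnovaGG:
    def test_two_conditions_have_epsilon_one(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.standard_normal((12, 2)))
        rep = rm_anova_gg(m)
        assert rep.epsilon == 1.0

    def test_epsilon_near_one_under_compound_symmetry(self):
        rng = np.random.default_rng(1)
        n, k = 200, 4
        subj = rng.normal(0, 2.0, size=(n, 1))
        x = subj + rng.standard_normal((n, k))
        assert gg_epsilon(x) == pytest.approx(1.0, abs=0.05)

    def test_epsilon_bounds(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.standard_normal((10, 5))
            eps = gg_epsilon(x)
            assert 1.0 / 4 <= eps <= 1.0

    def test_corrected_p_not_smaller_than_uncorrected(self):
        # for F > 1 shrinking both df by epsilon can only raise the p-value
        rng = np.random.default_rng(3)
        x = rng.standard_normal((15, 4)) + np.array([0, .6, 1.2, 1.8])
        rep = rm_anova_gg(_matrix(x))
        assert rep.statistic > 1.0
        p_uncorr = float(sst.f.sf(rep.statistic, 3, 3 * 14))
        assert rep.p >= p_uncorr

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        n, k = 20, 4
        x = rng.standard_normal((n, k)) + np.array([0, .3, .5, .9])
        x += rng.normal(0, 1.5, size=(n, 1))
        rep = rm_anova_gg(_matrix(x))
        long = pd.DataFrame({
            "y": x.ravel(),
            "cond": np.tile(np.arange(k), n),
            "subj": np.repeat(np.arange(n), k),
        })
        ref = pingouin.rm_anova(data=long, dv="y", within="cond",
                                subject="subj", correction=True)
        f_ref = float(ref["F"].iloc[0])
        eps_ref = float(ref["eps"].iloc[0])
        p_col = [c for c in ref.columns if "GG" in c][0]
        p_gg_ref = float(ref[p_col].iloc[0])
        assert rep.statistic == pytest.approx(f_ref, rel=1e-6)
        assert rep.epsilon == pytest.approx(eps_ref, rel=1e-6)
        assert rep.p == pytest.approx(p_gg_ref, rel=1e-6)

    def test_planted_monotone_effect_detected(self):
        rng = np.random.default_rng(6)
        n, k = 44, 8
        x = rng.normal(0, 0.5, (n, k)) + np.linspace(0, 1.0, k)
        x += rng.normal(0, 2.0, size=(n, 1))
        rep = rm_anova_gg(_matrix(x))
        assert rep.p < 0.001


class TestPosthoc:
    def test_adjustment_multiplies_by_pair_count(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((10, 4))
        x[:, 0] += 1.0
        m = _matrix(x)
        adj = posthoc_t_bonferroni(m)
        raw = sst.ttest_rel(x[:, 0], x[:, 1]).pvalue
        assert adj.iloc[0, 1] == pytest.approx(min(1.0, 6 * raw))

    def test_identical_columns_give_p_one(self):
        x = np.tile(np.arange(5, dtype=float)[:, None], (1, 3))
        adj = posthoc_t_bonferroni(_matrix(x))
        assert (adj.values == 1.0).all()

    def test_matrix_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(1)
        adj = posthoc_t_bonferroni(_matrix(rng.standard_normal((8, 4))))
        np.testing.assert_array_equal(adj.values, adj.values.T)
        np.testing.assert_array_equal(np.diag(adj.values), 1.0)

    def test_zero_variance_nonzero_difference(self):
        x = np.column_stack([np.arange(5.0), np.arange(5.0) + 2.0])
        with pytest.warns(UserWarning, match="zero-variance"):
            adj = posthoc_t_bonferroni(_matrix(x))
        assert adj.iloc[0, 1] == 0.0


class TestCohensD:
    def test_identical_groups(self):
        assert cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_known_value(self):
        assert cohens_d([1, 2, 3], [3, 4, 5]) == pytest.approx(-2.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.standard_normal(10), rng.standard_normal(12) + 0.5
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([2.0, 2.0], [3.0, 3.0])


class TestMixedMediation:
    def _spec(self):
        return MixedModelSpec(response="z_mean_scl", condition="speed",
                              moderator="group")

    def test_noiseless_recovery_to_three_decimals(self):
        from crowdeda.benchmark import simulate_moderation_data

        data = simulate_moderation_data(n_subjects=40, beta_speed=-0.8,
                                        beta_moderator=0.3,
                                        beta_interaction=0.1,
                                        noise_sd=0.0, seed=0)
        fit = mixed_mediation(data, self._spec())
        beta = fit.set_index("parameter")["beta"]
        assert beta["speed"] == pytest.approx(-0.8, abs=5e-4)
        assert beta["speed:group"] == pytest.approx(0.1, abs=5e-4)

    def test_null_interaction_within_two_se(self):
        from crowdeda.benchmark import simulate_moderation_data

        hits = 0
        for i in range(20):
            data = simulate_moderation_data(n_subjects=100, beta_speed=-0.8,
                                            beta_interaction=0.0,
                                            noise_sd=0.5, seed=50 + i)
            fit = mixed_mediation(data, self._spec())
            row = fit[fit.parameter == "speed:group"].iloc[0]
            se = abs(row.beta / row.t)
            hits += abs(row.beta) <= 2 * se
        assert hits >= 17

    def test_constant_moderator_rejected(self):
        from crowdeda.benchmark import simulate_moderation_data

        data = simulate_moderation_data(n_subjects=10, seed=0)
        data["group"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            mixed_mediation(data, self._spec())

    def test_matches_statsmodels_mixedlm_betas(self):
        from crowdeda.benchmark import simulate_moderation_data
        import statsmodels.formula.api as smf

        data = simulate_moderation_data(n_subjects=60, noise_sd=0.5, seed=9)
        fit = mixed_mediation(data, self._spec())
        ref = smf.mixedlm("z_mean_scl ~ speed * group", data,
                          groups=data["subject_id"]).fit(reml=True)
        beta = fit.set_index("parameter")["beta"]
        assert beta["speed"] == pytest.approx(ref.params["speed"], abs=1e-5)
        assert beta["speed:group"] == pytest.approx(
            ref.params["speed:group"], abs=1e-5)


class TestAnalyzeStudy:
    def _features(self, x, labels):
        n, k = x.shape
        return pd.DataFrame({
            "subject_id": np.repeat([f"s{i}" for i in range(n)], k),
            "label": np.tile(labels, n),
            "mean_scl": x.ravel(),
        })

    def test_normal_data_uses_rm_anova(self):
        rng = np.random.default_rng(0)
        labels = ["a", "b", "c"]
        x = rng.standard_normal((30, 3))
        reports = analyze_study(self._features(x, labels), ["mean_scl"],
                                labels=labels)
        assert reports["mean_scl"].test == "rm_anova_gg"

    def test_skewed_data_falls_back_to_friedman(self):
        rng = np.random.default_rng(1)
        labels = ["a", "b", "c"]
        x = rng.exponential(1.0, (30, 3)) ** 3
        reports = analyze_study(self._features(x, labels), ["mean_scl"],
                                labels=labels)
        assert reports["mean_scl"].test.startswith("friedman")

    def test_single_condition_rejected(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((10, 1))
        with pytest.raises(ValueError):
            analyze_study(self._features(x, ["a"]), ["mean_scl"],
                          labels=["a"])

    def test_planted_gradient_rejects_with_extreme_pair_posthocs(self):
        rng = np.random.default_rng(3)
        n, k = 44, 8
        labels = [f"n={v}" for v in (4, 8, 16, 20, 24, 32, 36, 40)]
        x = rng.normal(0, 0.6, (n, k)) + np.linspace(0, 1.2, k)
        x += rng.normal(0, 2.0, (n, 1))
        reports = analyze_study(self._features(x, labels), ["mean_scl"],
                                labels=labels)
        rep = reports["mean_scl"]
        assert rep.p < 0.05
        ph = rep.posthoc
        # significance concentrates in extreme-vs-extreme pairs
        assert ph.loc["n=4", "n=40"] < 0.05
        assert ph.loc["n=4", "n=36"] < 0.05
        assert ph.loc["n=16", "n=20"] > 0.05
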