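import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dosereg.differential_expression import (bh_fdr, call_de, fold_change,
                                             snk_posthoc, unpaired_ttest,
                                             welch_anova, welch_anova_matrix)
from dosereg.synthetic_data import SimulationConfig, simulate_expression

from conftest import ladder_design, ladder_matrix_from_log2, make_matrix


def bh_oracle(p):
    """Independent brute-force BH step-up: q_i = min_{j>=rank(i)} p_(j)*m/j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = min(running, 1.0)
    return q


class TestFoldChange:
    @pytest.mark.parametrize("a,b,expected", [
        (100.0, 150.0, 1.5), (150.0, 100.0, -1.5), (100.0, 100.0, 1.0)])
    def test_signed_convention(self, a, b, expected):
        fc_lin, fc_sgn = fold_change(a, b)
        assert fc_sgn == pytest.approx(expected)
        assert abs(fc_sgn) >= 1.0
        assert fc_lin == pytest.approx(b / a)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            fold_change(0.0, 10.0)

    def test_antisymmetric_under_contrast_swap(self):
        rng = np.random.default_rng(0)
        for a, b in rng.uniform(1, 1000, (50, 2)):
            if np.isclose(a, b):
                continue
            assert fold_change(a, b)[1] == pytest.approx(-fold_change(b, a)[1])


class TestTTest:
    def test_identical_groups_p_one(self):
        assert unpaired_ttest([1, 2, 3], [1, 2, 3]) == 1.0

    def test_pooled_matches_t_cdf_closed_form(self):
        # t = -12.247, df = 4 for these groups under the pooled test
        p = unpaired_ttest([10, 11, 12], [20, 21, 22], equal_var=True)
        t = -10 / np.sqrt(1.0 * (1 / 3 + 1 / 3))
        assert t == pytest.approx(-12.247, abs=1e-3)
        assert p == pytest.approx(2 * stats.t.cdf(t, df=4), rel=1e-10)

    def test_symmetric_in_group_order(self):
        a, b = [1.0, 2.5, 3.0], [4.0, 4.5, 6.0]
        assert unpaired_ttest(a, b) == pytest.approx(unpaired_ttest(b, a))
        assert unpaired_ttest(a, b, equal_var=False) == pytest.approx(
            unpaired_ttest(b, a, equal_var=False))


class TestWelchAnova:
    def test_identical_groups_p_one(self):
        g = [1.0, 2.0, 3.0]
        assert welch_anova([g, g, g, g]) == 1.0

    def test_two_groups_equals_welch_ttest(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.normal(0, 1, 4)
            b = rng.normal(0.5, 2, 6)
            p_anova = welch_anova([a, b])
            p_t = stats.ttest_ind(a, b, equal_var=False).pvalue
            assert p_anova == pytest.approx(p_t, rel=1e-9)

    def test_matches_independent_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd
        rng = np.random.default_rng(2)
        for _ in range(10):
            groups = [rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), 5)
                      for _ in range(4)]
            df = pd.DataFrame({
                "y": np.concatenate(groups),
                "g": np.repeat(np.arange(4), 5)})
            expected = pingouin.welch_anova(df, dv="y", between="g")["p_unc"][0]
            assert welch_anova(groups) == pytest.approx(expected, rel=1e-6)

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            welch_anova([[1.0], [1.0, 2.0]])

    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, (10_000, 4, 3))
        p = welch_anova_matrix([x[:, j] for j in range(4)])
        rate = (p < 0.05).mean()
        # binomial 99% CI around 0.05 at n=10,000 is ~(0.044, 0.056)
        assert 0.04 < rate < 0.06


class TestBHFDR:
    def test_step_up_hand_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.42])[0] == pytest.approx(0.42)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            p = rng.uniform(0, 1, rng.integers(1, 40))
            np.testing.assert_allclose(bh_fdr(p), bh_oracle(p), rtol=0, atol=0)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=50))
    def test_oracle_equality_property(self, p):
        np.testing.assert_array_equal(bh_fdr(p), bh_oracle(p))

    def test_matches_statsmodels(self):
        statsmodels = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(11)
        p = rng.uniform(0, 1, 500)
        np.testing.assert_allclose(bh_fdr(p),
                                   statsmodels.multipletests(p, method="fdr_bh")[1],
                                   atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    def test_q_at_least_p_and_order_preserving(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0, 1, 100)
        q = bh_fdr(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestSNK:
    def test_identical_groups_not_significant(self):
        g = [1.0, 2.0, 3.0]
        sig = snk_posthoc([g, [v + 0.001 for v in g]])
        assert not sig.to_numpy().any()

    def test_outlier_group_separated(self):
        rng = np.random.default_rng(6)
        groups = [rng.normal(0, 0.1, 3), rng.normal(0.1, 0.1, 3),
                  rng.normal(5, 0.1, 3)]
        sig = snk_posthoc(groups).to_numpy()
        assert sig[0, 2] and sig[1, 2] and not sig[0, 1]

    def test_two_groups_equals_pooled_t_decision(self):
        # for k=2, q = t*sqrt(2), so the SNK call matches the pooled t-test
        rng = np.random.default_rng(7)
        agreements = []
        for _ in range(30):
            a = rng.normal(0, 1, 4)
            b = rng.normal(rng.uniform(0, 2.5), 1, 4)
            snk_sig = snk_posthoc([a, b]).iloc[0, 1]
            t_sig = stats.ttest_ind(a, b, equal_var=True).pvalue < 0.05
            agreements.append(bool(snk_sig) == bool(t_sig))
        assert all(agreements)

    @pytest.mark.parametrize("k,df", [(2, 4), (3, 4), (4, 10)])
    def test_studentized_range_quantile_vs_monte_carlo(self, k, df):
        rng = np.random.default_rng(8)
        n = 200_000
        z = rng.normal(0, 1, (n, k))
        s = np.sqrt(rng.chisquare(df, n) / df)
        q = (z.max(axis=1) - z.min(axis=1)) / s
        q95_mc = np.quantile(q, 0.95)
        q95 = stats.studentized_range.ppf(0.95, k, df)
        # compare at the CDF level: MC quantile mapped through the CDF
        assert abs(stats.studentized_range.cdf(q95_mc, k, df) - 0.95) < 0.005
        assert q95 == pytest.approx(q95_mc, rel=0.02)


class TestCallDE:
    def test_null_matrix_makes_no_calls(self):
        rng = np.random.default_rng(9)
        m = ladder_matrix_from_log2(np.tile([8.0, 8, 8, 8], (500, 1)),
                                    noise_sd=0.15, rng=rng)
        res = call_de(m, ladder_design(3), ("WT", "Pax1KO_Pax9KO"))
        frac = np.mean([r.significant for r in res])
        assert frac <= 0.005

    def test_planted_gradual_down_genes_called(self):
        cfg = SimulationConfig(n_genes=400, noise_sd_log2=0.1,
                               class_counts={"group1_down": 100}, seed=10,
                               absent_fraction=0.0)
        m, design, truth = simulate_expression(cfg)
        res = call_de(m, design, ("WT", "Pax1KO_Pax9KO"))
        called_down = {r.gene_id for r in res if r.significant and r.fc_signed < 0}
        planted = set(truth.genes.loc[truth.genes["class"] == "group1_down", "gene_id"])
        assert len(called_down & planted) / len(planted) >= 0.9

    def test_zero_variance_identical_matrix(self):
        m = ladder_matrix_from_log2(np.tile([8.0, 8, 8, 8], (20, 1)))
        res = call_de(m, ladder_design(3), ("WT", "Pax1KO_Pax9KO"))
        assert all(not r.significant for r in res)
        assert all(r.p_raw == 1.0 for r in res)

    def test_underreplicated_contrast_rejected(self):
        m = ladder_matrix_from_log2(np.tile([8.0, 8, 8, 8], (5, 1)))
        with pytest.raises(ValueError):
            call_de(m, ladder_design(3), ("WT", "nonexistent"))
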