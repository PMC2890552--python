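import numpy as np
import pandas as pd
import pytest
from scipy import stats

from retqtl import diffexpr, normalize
from retqtl import synthetic_data as sim

from conftest import matrix_from_values


class TestOneGroupT:
    def test_symmetric_values_give_zero_t(self):
        mean, t, p = diffexpr.one_group_t(np.array([-1.0, 1.0, -1.0, 1.0]))
        assert mean == 0 and t == 0 and p == pytest.approx(1.0)

    def test_textbook_hand_computation(self):
        # mean 0.7, sd = sqrt((0.04 + 0.04)/3) = 0.16330, t = 0.7/(sd/2)
        mean, t, p = diffexpr.one_group_t(np.array([0.5, 0.7, 0.9, 0.7]))
        assert mean == pytest.approx(0.7)
        assert t == pytest.approx(8.573, abs=1e-3)
        assert p == pytest.approx(2 * stats.t.sf(t, 3))

    def test_constant_gene_flagged_degenerate(self):
        mean, t, p = diffexpr.one_group_t(np.array([0.3, 0.3, 0.3]))
        assert mean == pytest.approx(0.3)
        assert np.isnan(t) and np.isnan(p)

    def test_fewer_than_three_values_is_error(self):
        with pytest.raises(ValueError, match=">= 3"):
            diffexpr.one_group_t(np.array([1.0, 2.0]))

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(0)
        v = rng.normal(0.2, 1.0, 12)
        _, t, p = diffexpr.one_group_t(v)
        ref = stats.ttest_1samp(v, 0.0)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestComparisons:
    def test_age_restricted_effect_localized(self, tiny_design16):
        # effect Delta=1 planted only at 8 months, sigma=0.2, 8 chips per
        # age: the m8 comparison mean lands within 3 SE of 1, the m4 mean
        # within 3 SE of 0, for >90% of planted genes
        rng = np.random.default_rng(21)
        n_genes, delta, sigma = 200, 1.0, 0.2
        eff = rng.choice(n_genes, size=20, replace=False)
        vals = pd.DataFrame(rng.normal(0, sigma, (n_genes, 16)),
                            columns=tiny_design16.chip_ids)
        chips8 = tiny_design16.chips_with(age_months=8)
        vals.loc[eff, chips8] += delta
        mat = matrix_from_values(vals, tiny_design16,
                                 stage="dye_corrected_oriented")
        res = diffexpr.run_comparisons(mat, n_perm=100, seed=1)
        se = sigma / np.sqrt(8)
        m8 = res["m8"].loc[eff, "mean_log2_C_over_B6a"]
        m4 = res["m4"].loc[eff, "mean_log2_C_over_B6a"]
        assert (np.abs(m8 - delta) < 3 * se).mean() > 0.9
        assert (np.abs(m4) < 3 * se).mean() > 0.9

    def test_age_dependency_zero_for_equal_ages(self, tiny_design):
        # same per-gene chip values in the 4 m and 8 m subsets: t must vanish
        rng = np.random.default_rng(2)
        per_age = rng.normal(0, 1, (30, 4))
        chips4 = tiny_design.chips_with(age_months=4)
        chips8 = tiny_design.chips_with(age_months=8)
        vals = pd.DataFrame(index=range(30), columns=tiny_design.chip_ids,
                            dtype=float)
        for j, (c4, c8) in enumerate(zip(chips4, chips8)):
            vals[c4] = per_age[:, j]
            vals[c8] = per_age[:, j]
        mat = matrix_from_values(vals, tiny_design,
                                 stage="dye_corrected_oriented")
        res = diffexpr.run_comparisons(mat, n_perm=100, seed=0)
        assert np.abs(res["age_dependency"]["t_stat"]).max() < 1e-10

    def test_all_zero_matrix_gives_zero_means(self, tiny_design):
        rng = np.random.default_rng(4)
        vals = pd.DataFrame(rng.normal(0, 1e-9, (20, 8)),
                            columns=tiny_design.chip_ids)
        mat = matrix_from_values(vals, tiny_design,
                                 stage="dye_corrected_oriented")
        res = diffexpr.run_comparisons(mat, n_perm=100, seed=0)
        for comparison in ("all16", "m4", "m8"):
            assert np.abs(res[comparison]["mean_log2_C_over_B6a"]).max() < 1e-8

    def test_balanced_design_identity(self, normalized_default):
        # complete-data genes: all-chip mean == average of the two age means
        matrix, _, _ = normalized_default
        res = diffexpr.run_comparisons(matrix, n_perm=100, seed=0)
        complete = matrix.values.dropna().index
        lhs = res["all16"].loc[complete, "mean_log2_C_over_B6a"]
        rhs = 0.5 * (res["m4"].loc[complete, "mean_log2_C_over_B6a"]
                     + res["m8"].loc[complete, "mean_log2_C_over_B6a"])
        assert np.abs(lhs - rhs).max() < 1e-10

    def test_fc_is_two_to_the_mean(self, normalized_default):
        matrix, _, _ = normalized_default
        res = diffexpr.run_comparisons(matrix, n_perm=100, seed=0)
        for comparison in ("all16", "m4", "m8"):
            df = res[comparison]
            assert np.allclose(df["FC"], 2.0 ** df["mean_log2_C_over_B6a"])


class TestPermutationFdr:
    def test_null_data_gives_large_median_q(self, tiny_design):
        rng = np.random.default_rng(5)
        vals = pd.DataFrame(rng.normal(0, 1, (300, 8)),
                            columns=tiny_design.chip_ids)
        t = pd.Series(diffexpr._one_group_t_matrix(vals.to_numpy()),
                      index=vals.index)
        q = diffexpr.permutation_fdr(t, vals, "one_group", n_perm=200, seed=6)
        assert q.median() > 0.5

    def test_planted_signal_separated_from_null(self):
        # 20 genes with |t| >> 10 among 500 nulls: every planted gene must
        # reach q < 0.05; false positives among nulls stay rare. The FP
        # count at a fixed threshold is binomially variable, so the bound
        # is checked on the median over a few fixed seeds.
        fp_counts = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n_null, n_sig = 500, 20
            vals = np.vstack([
                rng.normal(0, 0.1, (n_null, 16)),
                rng.normal(1.0, 0.1, (n_sig, 16)),
            ])
            df = pd.DataFrame(vals,
                              index=[f"g{i}" for i in range(n_null + n_sig)],
                              columns=[f"c{j}" for j in range(16)])
            t = pd.Series(diffexpr._one_group_t_matrix(vals), index=df.index)
            q = diffexpr.permutation_fdr(t, df, "one_group", n_perm=300,
                                         seed=seed)
            assert (q.iloc[n_null:] < 0.05).all()
            fp_counts.append(int((q.iloc[:n_null] < 0.05).sum()))
        assert np.median(fp_counts) <= 3

    def test_single_gene_zero_t_capped_at_one(self):
        df = pd.DataFrame([[0.5, -0.5, 0.5, -0.5]], index=["g"],
                          columns=list("abcd"))
        t = pd.Series([0.0], index=["g"])
        q = diffexpr.permutation_fdr(t, df, "one_group", n_perm=100, seed=0)
        assert q["g"] == 1.0

    def test_q_monotone_in_abs_t(self, normalized_default):
        matrix, _, _ = normalized_default
        sub = matrix.values
        t = pd.Series(diffexpr._one_group_t_matrix(sub.to_numpy()),
                      index=sub.index)
        q = diffexpr.permutation_fdr(t, sub, "one_group", n_perm=150, seed=9)
        df = pd.DataFrame({"t": t.abs(), "q": q}).dropna().sort_values("t")
        assert (np.diff(df["q"]) <= 1e-12).all()

    def test_too_few_permutations_rejected(self):
        df = pd.DataFrame(np.ones((2, 4)), columns=list("abcd"))
        t = pd.Series([1.0, 2.0], index=df.index)
        with pytest.raises(ValueError, match="100"):
            diffexpr.permutation_fdr(t, df, "one_group", n_perm=50)

    def test_type_i_control_on_pure_null(self):
        # mean fraction of q < 0.05 calls across seeds stays below 0.05
        fracs = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            vals = pd.DataFrame(rng.normal(0, 1, (200, 16)),
                                columns=[f"c{j}" for j in range(16)])
            t = pd.Series(diffexpr._one_group_t_matrix(vals.to_numpy()),
                          index=vals.index)
            q = diffexpr.permutation_fdr(t, vals, "one_group", n_perm=150,
                                         seed=seed)
            fracs.append((q < 0.05).mean())
        assert np.mean(fracs) < 0.05


class TestRegulatedCall:
    @pytest.mark.parametrize(
        "fc,q,expected",
        [
            (0.8, 0.04, True),   # inclusive down boundary
            (1.2, 0.04, True),   # inclusive up boundary
            (1.1, 0.001, False),
            (2.0, 0.2, False),
            (0.5, 0.049, True),
            (1.0, 0.0001, False),
            (1.2, 0.05, False),  # FDR bound strict
        ],
    )
    def test_boundaries(self, fc, q, expected):
        assert diffexpr.call_regulated(fc, q) is expected

    def test_vectorized_matches_scalar(self):
        fc = pd.Series([0.8, 1.2, 1.0, 3.0])
        q = pd.Series([0.01, 0.1, 0.01, 0.01])
        out = diffexpr.call_regulated(fc, q)
        assert list(out) == [diffexpr.call_regulated(f, qq)
                             for f, qq in zip(fc, q)]
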