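import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polyload import SimParams, simulate_dataset
from polyload.formats import ExpressionMatrix
from polyload.loading import (
    class_composition,
    compare_ratio_distributions,
    fpkm,
    fpkm_matrix,
    loading_table,
    paired_loading_test,
    size_factors,
)


class TestFpkm:
    @pytest.mark.parametrize(
        "counts, length, lib, expected",
        [(1000, 1000, 1e6, 1000.0), (10, 2000, 1e7, 0.5), (0, 1500, 1e6, 0.0)],
    )
    def test_hand_values(self, counts, length, lib, expected):
        assert fpkm(counts, length, lib) == pytest.approx(expected)

    def test_scale_invariance(self, rng):
        counts = rng.integers(0, 1000, 50)
        lengths = rng.integers(200, 3000, 50)
        base = fpkm(counts, lengths, counts.sum())
        scaled = fpkm(counts * 7, lengths, (counts * 7).sum())
        np.testing.assert_allclose(base, scaled)

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            fpkm([1], [100], 0)


class TestSizeFactors:
    def test_identical_columns_give_unity(self):
        df = pd.DataFrame({"a": [10, 100, 1], "b": [10, 100, 1]})
        np.testing.assert_allclose(size_factors(df), [1.0, 1.0])

    def test_doubled_column_hand_value(self):
        df = pd.DataFrame({"a": [10, 100, 1], "b": [20, 200, 2]})
        np.testing.assert_allclose(size_factors(df), [2**-0.5, 2**0.5])

    def test_row_permutation_invariance(self, rng):
        df = pd.DataFrame(rng.integers(1, 500, (30, 3)))
        perm = df.sample(frac=1, random_state=1)
        np.testing.assert_allclose(size_factors(df), size_factors(perm))

    def test_all_zero_feature_handling(self):
        df = pd.DataFrame({"a": [0, 0], "b": [0, 5]})
        with pytest.raises(ValueError, match="nonzero"):
            size_factors(df)


class TestLoadingTable:
    def test_equal_fpkm_gives_zero_l(self, toy_expression):
        # make polysome counts equal cytosol counts
        counts = toy_expression.counts.copy()
        for s in ("S1", "S2"):
            counts[(s, "POLYSOME")] = counts[(s, "CYTOSOL")]
        expr = ExpressionMatrix(toy_expression.features, counts)
        table = loading_table(expr)
        np.testing.assert_allclose(table[["L_S1", "L_S2"]], 0.0, atol=1e-12)

    def test_hand_fold_change_with_pseudocount(self):
        # FPKM poly 7, cyt 1 with c0=1 -> log2(8/2) = 2
        features = pd.DataFrame(
            {"gene_id": ["g"], "rna_class": ["protein_coding"], "length_bases": [1000]},
            index=pd.Index(["f"], name="feature_id"),
        )
        cols = pd.MultiIndex.from_product([["S1", "S2"], ["CYTOSOL", "POLYSOME"]])
        # library size fixed at 1e6 by a single feature; counts chosen so FPKM = count
        counts = pd.DataFrame([[1, 7, 1, 7]], index=features.index, columns=cols)
        fk = fpkm_matrix(ExpressionMatrix(features, counts))
        l = np.log2((fk[("S1", "POLYSOME")] + 1) / (fk[("S1", "CYTOSOL")] + 1))
        # single feature: FPKM = 1e9/(1000 * count_total) * count; compute directly
        expected = np.log2((fpkm(7, 1000, 7) + 1) / (fpkm(1, 1000, 1) + 1))
        assert l.iloc[0] == pytest.approx(expected)

    def test_paired_test_matches_t_distribution_oracle(self):
        l = np.array([[1.0, 1.1, 0.9]])
        p, q = paired_loading_test(l)
        mean, sd = l.mean(), l.std(ddof=1)
        t = mean / (sd / np.sqrt(3))
        expected = 2 * stats.t.sf(abs(t), df=2)
        assert p[0] == pytest.approx(expected, abs=1e-10)
        assert q[0] >= p[0]

    def test_all_zero_l_vector_p_one(self):
        p, _ = paired_loading_test(np.zeros((1, 3)))
        assert p[0] == 1.0

    def test_bh_step_up_hand_example(self):
        # p = (0.01, 0.02, 0.03), m = 3 -> q = (0.03, 0.03, 0.03)
        from statsmodels.stats.multitest import multipletests

        q = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        np.testing.assert_allclose(q, [0.03, 0.03, 0.03])

    def test_null_p_values_uniform(self):
        # lambda = 1 null: two-sided p-values uniform within KS 0.05
        rng = np.random.default_rng(42)
        n_feat, disp = 2000, 10.0
        mu = 500 * np.exp(rng.normal(0, 0.5, n_feat))
        pnb = disp / (disp + mu)
        l = np.empty((n_feat, 3))
        for s in range(3):
            c = rng.negative_binomial(disp, pnb).astype(float)
            q_ = rng.negative_binomial(disp, pnb).astype(float)
            fc = c * 1e9 / (1500 * c.sum())
            fq = q_ * 1e9 / (1500 * q_.sum())
            l[:, s] = np.log2((fq + 1) / (fc + 1))
        p, _ = paired_loading_test(l)
        assert stats.kstest(p, "uniform").statistic < 0.05


class TestClassComposition:
    def test_percentages_sum_to_100(self, toy_expression):
        comp = class_composition(toy_expression)
        sums = comp.groupby(["sample_id", "fraction"])["percent"].sum()
        np.testing.assert_allclose(sums, 100.0)

    def test_two_class_split_hand_value(self):
        features = pd.DataFrame(
            {
                "gene_id": ["g1", "g2"],
                "rna_class": ["protein_coding", "lincRNA"],
                "length_bases": [1000, 1000],
            },
            index=pd.Index(["f1", "f2"], name="feature_id"),
        )
        cols = pd.MultiIndex.from_tuples([("S1", "CYTOSOL")])
        counts = pd.DataFrame([[30], [70]], index=features.index, columns=cols)
        comp = class_composition(ExpressionMatrix(features, counts)).set_index("rna_class")
        assert comp.loc["lincRNA", "percent"] == pytest.approx(70.0)
        assert comp.loc["protein_coding", "percent"] == pytest.approx(30.0)

    def test_simulated_lncRNA_depleted_on_polysomes(self, small_dataset):
        comp = class_composition(
            small_dataset.expression, size_factors(small_dataset.expression.counts)
        )
        lnc = comp[comp["rna_class"].str.startswith(("lncRNA", "lincRNA"))]
        share = lnc.groupby("fraction")["percent"].sum() / 3  # 3 samples
        assert share["POLYSOME"] < share["CYTOSOL"]


class TestCompareRatioDistributions:
    def test_identical_vectors_chi2_zero(self, rng):
        x = rng.normal(size=200)
        chi2, df, p = compare_ratio_distributions(x, x.copy())
        assert chi2 == 0.0
        assert p == 1.0
        assert df >= 1

    def test_hand_two_by_two(self):
        # construct data landing in exactly two merged bins: a 30/10, b 10/30
        a = np.concatenate([np.zeros(30), np.ones(10)])
        b = np.concatenate([np.zeros(10), np.ones(30)])
        chi2, df, p = compare_ratio_distributions(a, b, n_bins=2)
        assert chi2 == pytest.approx(20.0)
        assert df == 1

    def test_symmetry(self, rng):
        a = rng.normal(0, 1, 150)
        b = rng.normal(0.5, 1.2, 180)
        s1 = compare_ratio_distributions(a, b)
        s2 = compare_ratio_distributions(b, a)
        assert s1[0] == pytest.approx(s2[0])

    def test_detects_shifted_class_on_simulation(self, small_dataset):
        sf = size_factors(small_dataset.expression.counts)
        table = loading_table(small_dataset.expression, sf)
        coding = table.loc[table["rna_class"] == "protein_coding", "mean_L"]
        noncoding = table.loc[table["rna_class"] != "protein_coding", "mean_L"]
        chi2, df, p = compare_ratio_distributions(coding, noncoding)
        assert p < 0.05
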