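import numpy as np
import pandas as pd
import pytest

from polyload.allelic import gene_aei_table, snp_ratio_table
from polyload.formats import ExpressionMatrix
from polyload.isoforms import cross_aei_isoforms, detect_isoform_shift, isoform_fractions


def _usage_df(rows):
    return pd.DataFrame(rows, columns=["isoform_id", "gene_id", "sample_id", "fraction", "f"])


def _expr(iso_counts, lengths=None):
    """Single-sample two-fraction matrix from {iso: (gene, cyt, poly)}."""
    ids = list(iso_counts)
    lengths = lengths or {i: 1000 for i in ids}
    features = pd.DataFrame(
        {
            "gene_id": [iso_counts[i][0] for i in ids],
            "rna_class": ["protein_coding"] * len(ids),
            "length_bases": [lengths[i] for i in ids],
        },
        index=pd.Index(ids, name="feature_id"),
    )
    cols = pd.MultiIndex.from_tuples([("S1", "CYTOSOL"), ("S1", "POLYSOME")])
    counts = pd.DataFrame(
        [[iso_counts[i][1], iso_counts[i][2]] for i in ids], index=features.index, columns=cols
    )
    return ExpressionMatrix(features, counts)


class TestIsoformFractions:
    def test_two_isoform_split(self):
        expr = _expr({"a.t0": ("a", 30, 30), "a.t1": ("a", 70, 70)})
        usage = isoform_fractions(expr).set_index(["isoform_id", "fraction"])
        assert usage.loc[("a.t0", "CYTOSOL"), "f"] == pytest.approx(0.3)
        assert usage.loc[("a.t1", "POLYSOME"), "f"] == pytest.approx(0.7)

    def test_three_isoform_hand_values(self):
        expr = _expr(
            {"a.t0": ("a", 10, 10), "a.t1": ("a", 10, 10), "a.t2": ("a", 20, 20)}
        )
        usage = isoform_fractions(expr)
        cyt = usage[usage["fraction"] == "CYTOSOL"].sort_values("isoform_id")
        np.testing.assert_allclose(cyt["f"], [0.25, 0.25, 0.5])

    def test_usage_sums_to_one_per_gene(self, small_dataset):
        usage = isoform_fractions(small_dataset.expression)
        sums = usage.groupby(["gene_id", "sample_id", "fraction"])["f"].sum()
        np.testing.assert_allclose(sums, 1.0)

    def test_length_bias_removed_by_fpkm(self):
        # equal molar usage, unequal lengths: counts differ but f is 50/50
        expr = _expr(
            {"a.t0": ("a", 100, 100), "a.t1": ("a", 300, 300)},
            lengths={"a.t0": 1000, "a.t1": 3000},
        )
        usage = isoform_fractions(expr)
        np.testing.assert_allclose(usage["f"], 0.5)

    def test_zero_gene_skipped(self):
        expr = _expr({"a.t0": ("a", 0, 10), "b.t0": ("b", 5, 5)})
        usage = isoform_fractions(expr)
        assert ("a.t0" in set(usage["isoform_id"])) and (
            usage[(usage.isoform_id == "a.t0") & (usage.fraction == "CYTOSOL")].empty
        )


class TestDetectIsoformShift:
    @pytest.mark.parametrize(
        "f_cyt, f_poly, flagged, direction",
        [
            (0.67, 0.31, True, "polysome_depleted"),
            (0.60, 0.83, True, "polysome_enriched"),
            (0.50, 0.60, False, "none"),
        ],
    )
    def test_threshold_and_direction(self, f_cyt, f_poly, flagged, direction):
        usage = _usage_df(
            [
                ("i", "g", "S1", "CYTOSOL", f_cyt),
                ("i", "g", "S1", "POLYSOME", f_poly),
            ]
        )
        out = detect_isoform_shift(usage)
        assert out["shift_flag"].iloc[0] == flagged
        assert out["direction"].iloc[0] == direction
        assert out["delta"].iloc[0] == pytest.approx(f_poly - f_cyt)

    def test_single_isoform_gene_never_shifts(self):
        usage = _usage_df(
            [("i", "g", "S1", "CYTOSOL", 1.0), ("i", "g", "S1", "POLYSOME", 1.0)]
        )
        out = detect_isoform_shift(usage)
        assert not out["shift_flag"].iloc[0]
        assert out["delta"].iloc[0] == 0.0

    def test_strict_mode_requires_all_samples(self):
        rows = [
            ("i", "g", "S1", "CYTOSOL", 0.6), ("i", "g", "S1", "POLYSOME", 0.1),
            ("i", "g", "S2", "CYTOSOL", 0.6), ("i", "g", "S2", "POLYSOME", 0.55),
        ]
        usage = _usage_df(rows)
        assert detect_isoform_shift(usage, mode="mean")["shift_flag"].iloc[0]
        assert not detect_isoform_shift(usage, mode="strict")["shift_flag"].iloc[0]

    def test_delta_sums_to_zero_over_gene(self, small_dataset):
        usage = isoform_fractions(small_dataset.expression)
        shifts = detect_isoform_shift(usage)
        sums = shifts.groupby("gene_id")["delta"].sum()
        np.testing.assert_allclose(sums, 0.0, atol=1e-9)


class TestCrossAeiIsoforms:
    @pytest.fixture()
    def aei_table(self):
        allele = pd.DataFrame(
            [
                # gFRG-like: balanced cytosol, imbalanced polysome
                ("S1", "CYTOSOL", "gFRG", "rs1", 50, 50),
                ("S1", "POLYSOME", "gFRG", "rs1", 73, 27),
                ("S1", "GDNA", "gFRG", "rs1", 50, 50),
                # gFlat: same AEI in both fractions
                ("S1", "CYTOSOL", "gFlat", "rs2", 70, 30),
                ("S1", "POLYSOME", "gFlat", "rs2", 70, 30),
                ("S1", "GDNA", "gFlat", "rs2", 50, 50),
            ],
            columns=["sample_id", "fraction", "gene_id", "snp_id", "ref_count", "alt_count"],
        )
        return gene_aei_table(snp_ratio_table(allele))

    def test_partition_by_fraction_difference(self, aei_table):
        shifts = pd.DataFrame(
            {
                "isoform_id": ["gFRG.t0", "gFlat.t0"],
                "gene_id": ["gFRG", "gFlat"],
                "f_cyt": [0.67, 0.60],
                "f_poly": [0.31, 0.83],
                "delta": [-0.36, 0.23],
                "shift_flag": [True, True],
                "direction": ["polysome_depleted", "polysome_enriched"],
                "major_flag": [True, True],
            }
        )
        cross = cross_aei_isoforms(shifts, aei_table).set_index("gene_id")
        assert cross.loc["gFRG", "aei_class"] == "aei_with_fraction_difference"
        assert cross.loc["gFRG", "D"] == pytest.approx(2.7, abs=0.05)
        assert cross.loc["gFlat", "aei_class"] == "aei_without_fraction_difference"

    def test_unflagged_isoforms_absent(self, aei_table):
        shifts = pd.DataFrame(
            {
                "isoform_id": ["gFRG.t0"],
                "gene_id": ["gFRG"],
                "f_cyt": [0.5],
                "f_poly": [0.45],
                "delta": [-0.05],
                "shift_flag": [False],
                "direction": ["none"],
                "major_flag": [False],
            }
        )
        assert cross_aei_isoforms(shifts, aei_table).empty

    def test_major_only_restriction(self, aei_table):
        shifts = pd.DataFrame(
            {
                "isoform_id": ["gFRG.t0"],
                "gene_id": ["gFRG"],
                "f_cyt": [0.40],
                "f_poly": [0.12],
                "delta": [-0.28],
                "shift_flag": [True],
                "direction": ["polysome_depleted"],
                "major_flag": [False],
            }
        )
        assert cross_aei_isoforms(shifts, aei_table, major_only=True).empty
        assert len(cross_aei_isoforms(shifts, aei_table, major_only=False)) == 1


class TestRecoveryOnSimulation:
    def test_shift_recovery_and_null_rate(self):
        from polyload import SimParams, simulate_dataset
        from polyload.loading import size_factors

        params = SimParams(
            n_genes=150, pi_isoform_shift=0.4, isoform_shift_delta=0.3,
            mean_expression=2000, expression_sigma=0.3, seed=77,
        )
        ds = simulate_dataset(params)
        usage = isoform_fractions(ds.expression, size_factors(ds.expression.counts))
        shifts = detect_isoform_shift(usage)
        truth = ds.truth.isoforms
        shifted_genes = set(truth.loc[truth["shifted"], "gene_id"])
        flagged_genes = set(shifts.loc[shifts["shift_flag"], "gene_id"])
        sens = len(shifted_genes & flagged_genes) / len(shifted_genes)
        null = shifts[~shifts["gene_id"].isin(shifted_genes)]
        assert sens >= 0.9
        assert null["shift_flag"].mean() <= 0.05
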