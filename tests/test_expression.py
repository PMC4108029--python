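"""Replicate merging, isoform-usage analytics, switching matrix, PCA and
panel differential tests."""

import numpy as np
import pandas as pd
import pytest

from splicescape.core import PipelineThresholds
from splicescape.expression import (
    ExpressionTable,
    group_differential,
    isoform_sharing,
    major_isoform,
    merge_replicates,
    pca_scores,
    summarize_isoform_usage,
    switching_matrix,
)
from splicescape.simulate import simulate_expression_design

from oracles import oracle_bh


def table(rows):
    return ExpressionTable(
        pd.DataFrame(rows, columns=["isoform", "gene", "sample", "replicate", "fpkm"])
    )


def two_iso_table(values):
    """values: {(iso, sample): (rep1, rep2)} over isoforms i1,i2 of gene g."""
    rows = []
    for (iso, sample), (r1, r2) in values.items():
        rows.append((iso, "g", sample, 1, r1))
        rows.append((iso, "g", sample, 2, r2))
    return table(rows)


class TestMergeReplicates:
    def test_detection_requires_both_replicates(self):
        m = merge_replicates(
            two_iso_table({("i1", "s1"): (1.2, 0.8), ("i2", "s1"): (2.0, 4.0)})
        )
        assert not m.detected.at["i1", "s1"]
        assert m.detected.at["i2", "s1"]
        assert m.values.at["i2", "s1"] == 3.0
        assert np.isnan(m.values.at["i1", "s1"])

    def test_zero_is_not_detected(self):
        m = merge_replicates(two_iso_table({("i1", "s1"): (0.0, 0.0), ("i2", "s1"): (1.0, 1.0)}))
        assert not m.detected.at["i1", "s1"]

    def test_missing_replicate_errors(self):
        rows = [("i1", "g", "s1", 1, 2.0)]
        with pytest.raises(ValueError, match="replicate"):
            table(rows)

    def test_gene_level_sums_detected_isoforms(self):
        m = merge_replicates(
            two_iso_table({("i1", "s1"): (2.0, 4.0), ("i2", "s1"): (0.5, 0.5)})
        )
        assert m.gene_values().at["g", "s1"] == 3.0


class TestMajorIsoform:
    def test_argmax(self):
        m = merge_replicates(two_iso_table({("i1", "s1"): (9, 9), ("i2", "s1"): (4, 4)}))
        assert major_isoform(m, "g", "s1") == "i1"

    def test_tie_breaks_to_smallest_id(self):
        m = merge_replicates(two_iso_table({("i2", "s1"): (3, 3), ("i1", "s1"): (3, 3)}))
        assert major_isoform(m, "g", "s1") == "i1"

    def test_none_when_undetected(self):
        m = merge_replicates(two_iso_table({("i1", "s1"): (0.5, 0.5), ("i2", "s1"): (0.2, 0.2)}))
        assert major_isoform(m, "g", "s1") is None

    def test_unknown_gene_errors(self):
        m = merge_replicates(two_iso_table({("i1", "s1"): (1, 1), ("i2", "s1"): (1, 1)}))
        with pytest.raises(KeyError):
            major_isoform(m, "nope", "s1")


class TestSharing:
    def test_identical_detection_is_fully_shared(self):
        m = merge_replicates(
            two_iso_table(
                {("i1", "s1"): (2, 2), ("i1", "s2"): (2, 2),
                 ("i2", "s1"): (2, 2), ("i2", "s2"): (2, 2)}
            )
        )
        res = isoform_sharing(m, {"s1": "A", "s2": "B"})
        assert res["shared_all_percent"] == 100.0

    def test_group_private_isoform_lands_in_private_region(self):
        m = merge_replicates(
            two_iso_table(
                {("i1", "s1"): (2, 2), ("i1", "s2"): (2, 2),
                 ("i2", "s1"): (2, 2), ("i2", "s2"): (0.1, 0.1)}
            )
        )
        res = isoform_sharing(m, {"s1": "A", "s2": "B"})
        assert res["region_counts"] == {"A": 1, "A&B": 1}

    def test_requires_two_groups(self):
        m = merge_replicates(two_iso_table({("i1", "s1"): (2, 2), ("i2", "s1"): (2, 2)}))
        with pytest.raises(ValueError):
            isoform_sharing(m, {"s1": "A"})


class TestUsageSummary:
    def test_planted_dominance_gives_ratio_fraction_one(self):
        m = merge_replicates(
            two_iso_table(
                {("i1", "s1"): (20, 20), ("i2", "s1"): (2, 2),
                 ("i1", "s2"): (30, 30), ("i2", "s2"): (3, 3)}
            )
        )
        s = summarize_isoform_usage(m)
        assert s["frac_ratio_ge2"] == 1.0 and s["frac_ratio_ge5"] == 1.0
        assert s["recurrence_fraction"] == 1.0

    def test_single_isoform_genes_have_no_ratios(self):
        rows = [("i1", "g", "s1", 1, 5.0), ("i1", "g", "s1", 2, 5.0),
                ("i1", "g", "s2", 1, 5.0), ("i1", "g", "s2", 2, 5.0)]
        s = summarize_isoform_usage(merge_replicates(table(rows)))
        assert s["top2_ratios"] == [] and set(s["coexpressed_counts"]) == {1}


class TestSwitchingMatrix:
    def test_log2_ratio(self):
        m = merge_replicates(
            two_iso_table(
                {("i1", "s1"): (6, 6), ("i2", "s1"): (3, 3),
                 ("i1", "s2"): (4, 4), ("i2", "s2"): (16, 16)}
            )
        )
        sw = switching_matrix(m)
        # i2 carries the higher summed FPKM, so it is designated first
        assert sw.designation["g"] == ("i2", "i1")
        assert sw.log_ratios.at["g", "s1"] == pytest.approx(-1.0)
        assert sw.log_ratios.at["g", "s2"] == pytest.approx(2.0)

    def test_undetected_partner_floored_at_detection(self):
        m = merge_replicates(
            two_iso_table(
                {("i1", "s1"): (8, 8), ("i2", "s1"): (0.5, 0.5),
                 ("i1", "s2"): (8, 8), ("i2", "s2"): (2, 2)}
            )
        )
        sw = switching_matrix(m)
        assert sw.log_ratios.at["g", "s1"] == pytest.approx(3.0)  # 8 vs floor 1.0

    def test_single_isoform_gene_absent(self):
        rows = [("i1", "g", "s1", 1, 5.0), ("i1", "g", "s1", 2, 5.0),
                ("i1", "g", "s2", 1, 5.0), ("i1", "g", "s2", 2, 5.0)]
        sw = switching_matrix(merge_replicates(table(rows)))
        assert len(sw.log_ratios) == 0

    def test_antisymmetric_under_designation_swap(self):
        m = merge_replicates(
            two_iso_table(
                {("i1", "s1"): (6, 6), ("i2", "s1"): (3, 3),
                 ("i1", "s2"): (4, 4), ("i2", "s2"): (8, 8)}
            )
        )
        sw = switching_matrix(m)
        iso1, iso2 = sw.designation["g"]
        flipped = np.log2(
            m.values.loc[iso2].fillna(1.0) / m.values.loc[iso1].fillna(1.0)
        )
        assert np.allclose(sw.log_ratios.loc["g"].to_numpy(), -flipped.to_numpy())


class TestPCA:
    def test_duplicate_samples_coincide(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(4, 10))
        X[3] = X[2]
        scores, _ = pca_scores(X, 2)
        assert np.allclose(scores[2], scores[3])

    def test_variance_conservation(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 5))
        scores, var = pca_scores(X, 5)
        total = ((X - X.mean(0)) ** 2).sum() / (X.shape[0] - 1)
        assert np.isclose(var.sum(), total)
        assert np.all(np.diff(var) <= 1e-9)

    def test_constant_matrix_gives_zero_variance(self):
        scores, var = pca_scores(np.ones((4, 3)), 2)
        assert np.allclose(var, 0)

    def test_missing_values_error(self):
        X = np.ones((3, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            pca_scores(X)


class TestGroupDifferential:
    def _values(self, shift=0.0, n_feat=20, seed=0):
        rng = np.random.default_rng(seed)
        cols = [f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)]
        X = rng.normal(size=(n_feat, 10))
        X[:, 5:] += shift
        grouping = {c: c[0] for c in cols}
        return pd.DataFrame(X, index=[f"f{i}" for i in range(n_feat)], columns=cols), grouping

    def test_identical_groups_not_significant(self, th):
        values, grouping = self._values(shift=0.0)
        res = group_differential(values, grouping, th=th)
        assert not res["significant"].any()

    def test_planted_large_shift_detected(self, th):
        values, grouping = self._values(shift=5.0)
        res = group_differential(values, grouping, th=th)
        assert res["significant"].all()

    def test_zero_variance_feature_flagged(self, th):
        values, grouping = self._values()
        values.loc["f0"] = 1.0
        res = group_differential(values, grouping, th=th)
        assert res.at["f0", "zero_variance"] and res.at["f0", "p"] == 1.0

    def test_bh_qvalues_match_sort_and_step_oracle(self, th):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(3, 40))
            values, grouping = self._values(shift=rng.uniform(0, 2), n_feat=n,
                                            seed=int(rng.integers(0, 1000)))
            res = group_differential(values, grouping, th=th)
            assert np.allclose(res["q"].to_numpy(), oracle_bh(res["p"].to_numpy()))


class TestDetectionMonotonicity:
    def test_raising_detection_threshold_shrinks_everything(self):
        tab, _ = simulate_expression_design(None, n_genes=40, seed=3)
        low = merge_replicates(tab, PipelineThresholds(detection_fpkm=1.0))
        high = merge_replicates(tab, PipelineThresholds(detection_fpkm=5.0))
        assert (high.detected & ~low.detected).to_numpy().sum() == 0
        assert high.detected.to_numpy().sum() <= low.detected.to_numpy().sum()
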