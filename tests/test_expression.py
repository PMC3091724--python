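"""Expression integration: fold changes, segment mapping, t-tests, filters."""

import math

import numpy as np
import pandas as pd
import pytest

from cnnloh import expression
from cnnloh.io import SEGMENT_COLUMNS


def seg(case, chrom, start, end, loh, group):
    return (case, chrom, start, end, loh, group, 5)


def segments_frame(rows):
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def gene_frame(rows):
    return pd.DataFrame(rows, columns=["probeset_id", "gene_symbol", "chrom",
                                       "start", "end"])


class TestFoldChanges:
    def test_subtraction_and_linear_fold(self):
        en = pd.DataFrame({"c1": [5.0]}, index=["p1"])
        et = pd.DataFrame({"c1": [6.0]}, index=["p1"])
        fc = expression.fold_changes(en, et)
        assert fc.iloc[0, 0] == 1.0 and 2 ** fc.iloc[0, 0] == 2.0

    def test_identical_matrices_zero(self):
        en = pd.DataFrame(np.ones((3, 2)), columns=["a", "b"])
        assert (expression.fold_changes(en, en) == 0).all().all()

    def test_unmatched_cases_rejected(self):
        en = pd.DataFrame({"c1": [5.0]})
        et = pd.DataFrame({"c2": [6.0]})
        with pytest.raises(ValueError, match="unmatched"):
            expression.fold_changes(en, et)


class TestMapGenes:
    def test_containment_straddle_and_gap(self):
        genes = gene_frame([
            ("p1", "G1", 1, 1000, 2000),   # inside the CNNLOH segment
            ("p2", "G2", 1, 4500, 6000),   # straddles two segments
            ("p3", "G3", 2, 100, 200),     # chromosome with no segments
        ])
        segs = segments_frame([
            seg("c1", 1, 500, 5000, True, "neutral"),
            seg("c1", 1, 5001, 9000, False, "gain"),
        ])
        loh, group = expression.map_genes(genes, segs, ["c1"])
        assert (loh[0, 0], group[0, 0]) == (1, 1)
        assert loh[1, 0] == expression.UNDEF and loh[2, 0] == expression.UNDEF

    def test_distinct_probesets_of_one_gene_map_independently(self):
        genes = gene_frame([("p1", "G", 1, 1000, 2000), ("p2", "G", 1, 4000, 7000)])
        segs = segments_frame([seg("c1", 1, 500, 3000, True, "neutral")])
        loh, _ = expression.map_genes(genes, segs, ["c1"])
        assert loh[0, 0] == 1 and loh[1, 0] == expression.UNDEF


class TestEligibility:
    def make_states(self, n_loh, n_noloh, n_undef=0, cn=1):
        n = n_loh + n_noloh + n_undef
        loh = np.array([[1] * n_loh + [0] * n_noloh + [-1] * n_undef], dtype=np.int8)
        group = np.full((1, n), cn, dtype=np.int8)
        group[0, n_loh + n_noloh:] = -1
        return loh, group

    @pytest.mark.parametrize("n_loh,n_noloh,ok", [(2, 13, True), (1, 16, False),
                                                  (2, 1, False), (8, 9, True)])
    def test_two_by_two_threshold(self, n_loh, n_noloh, ok):
        loh, group = self.make_states(n_loh, n_noloh)
        got = expression.eligible(loh, group, cn_class=1)
        assert (len(got) == 1) == ok

    def test_undefined_cases_excluded_from_both_groups(self):
        loh, group = self.make_states(2, 2, n_undef=13)
        got = expression.eligible(loh, group, cn_class=1)
        assert got["n_loh"].iat[0] == 2 and got["n_noloh"].iat[0] == 2

    def test_class_membership_is_per_class(self):
        loh, group = self.make_states(3, 3, cn=2)  # gain class
        assert len(expression.eligible(loh, group, cn_class=1)) == 0
        assert len(expression.eligible(loh, group, cn_class=2)) == 1


def hand_pooled_t(x, y):
    """Closed-form pooled-variance two-sample t (independent oracle)."""
    n1, n2 = len(x), len(y)
    s2 = ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / (n1 + n2 - 2)
    return (np.mean(x) - np.mean(y)) / math.sqrt(s2 * (1 / n1 + 1 / n2))


class TestLohTTest:
    def test_matches_closed_form(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(0, 1, 4), rng.normal(0.5, 1, 7)
        res = expression.loh_t_test(x, y)
        # reported t follows the (non-LOH minus LOH) orientation
        assert res["t_statistic"] == pytest.approx(hand_pooled_t(y, x))

    def test_strong_shift_significant_and_directed(self):
        rng = np.random.default_rng(1)
        x = np.array([-2.0, -2.0]) + rng.normal(0, 0.01, 2)
        y = rng.normal(0, 0.01, 3)
        res = expression.loh_t_test(x, y)
        assert res["p_value"] < 0.01 and res["significant"]
        assert res["direction"] == "lower_in_LOH" and res["t_statistic"] > 0

    def test_zero_variance_flagged_untestable(self):
        res = expression.loh_t_test(np.ones(3), np.ones(3))
        assert res["untestable"] and not res["significant"]
        assert math.isnan(res["p_value"])

    def test_group_of_one_rejected(self):
        with pytest.raises(ValueError):
            expression.loh_t_test(np.array([1.0]), np.array([1.0, 2.0]))

    def test_geometric_mean_fold_changes(self):
        res = expression.loh_t_test(np.array([1.0, 3.0]), np.array([0.0, 0.1, -0.1]))
        assert res["mean_fc_loh"] == pytest.approx(2 ** 2.0)
        assert res["mean_fc_noloh"] == pytest.approx(2 ** 0.0)


class TestTwofoldFilter:
    @pytest.mark.parametrize("fc,expected", [
        (0.404, True),   # strong down-shift in the LOH group
        (2.208, True),   # strong up-shift
        (0.51, False),   # between 0.5 and 2: not a 2-fold change
        (2.0, True), (0.5, True), (1.0, False),
    ])
    def test_rule(self, fc, expected):
        assert expression.twofold_filter(fc) is expected


class TestExpectedFalsePositives:
    @pytest.mark.parametrize("n,alpha,expected", [(4572, 0.01, 45), (100, 0.05, 5),
                                                  (0, 0.01, 0)])
    def test_integer_part(self, n, alpha, expected):
        assert expression.expected_false_positives(n, alpha) == expected

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            expression.expected_false_positives(10, 1.5)


class TestSnpCounting:
    def test_inclusive_interval_count(self, toy_map):
        # positions 100..1000 step 100; [50, 250] contains 100 and 200
        assert expression.count_snps_in_region(1, 50, 250, toy_map) == 2

    def test_empty_region(self, toy_map):
        assert expression.count_snps_in_region(1, 1001, 2000, toy_map) == 0

    def test_sibling_probesets_counted_independently(self, toy_map):
        a = expression.count_snps_in_region(1, 50, 250, toy_map)
        b = expression.count_snps_in_region(1, 50, 450, toy_map)
        assert (a, b) == (2, 4)


class TestPipelineAgreement:
    def test_direction_and_twofold_recomputed_brute_force(self, default_result):
        """Reported direction/twofold agree with a pass over raw fold changes."""
        res = default_result.expression_results
        cohort = default_result.cohort
        fc = (cohort.expr_tumor - cohort.expr_normal)
        from cnnloh.expression import map_genes

        genes = cohort.genes.set_index("probeset_id").loc[fc.index].reset_index()
        loh, group = map_genes(genes, default_result.segments, list(fc.columns))
        class_code = {"neutral": 1, "loss": 0, "gain": 2}
        checked = 0
        for row in res.itertuples(index=False):
            i = genes.index[genes["probeset_id"] == row.probeset_id][0]
            cls = class_code[row.cn_class]
            sel = group[i] == cls
            x = fc.iloc[i].to_numpy()[sel & (loh[i] == 1)]
            y = fc.iloc[i].to_numpy()[sel & (loh[i] == 0)]
            want_dir = "lower_in_LOH" if x.mean() < y.mean() else "higher_in_LOH"
            assert row.direction == want_dir
            mean_fc = 2 ** x.mean()
            assert row.twofold == (mean_fc >= 2 or mean_fc <= 0.5)
            checked += 1
        assert checked == len(res) > 0
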