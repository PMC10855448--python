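import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import refstab as rs

from conftest import make_ct


def two_gene_matrix(target_cts, norm_cts, groups=None):
    arr = np.column_stack([target_cts, norm_cts])
    return make_ct(arr, genes=["T", "N"], groups=groups,
                   gene_role={"T": "target"})


class TestRelativeExpression:
    @pytest.mark.parametrize(
        "delta, expected", [(0.0, 1.0), (1.0, 0.5), (-10.0, 1024.0)]
    )
    def test_two_power_minus_delta_ct(self, delta, expected):
        m = two_gene_matrix([20.0 + delta] * 3, [20.0] * 3)
        e = rs.relative_expression(m, ["T"], "N")
        np.testing.assert_allclose(e.q["T"], expected)

    def test_normalizer_as_target_warns_and_gives_one(self):
        m = two_gene_matrix([20.0] * 3, [18.0] * 3)
        with pytest.warns(UserWarning, match="also a target"):
            e = rs.relative_expression(m, ["N"], "N")
        np.testing.assert_allclose(e.q["N"], 1.0)

    def test_missing_ct_rejected(self):
        m = two_gene_matrix([20.0, np.nan, 21.0], [18.0] * 3)
        with pytest.raises(rs.ValidationError, match="missing"):
            rs.relative_expression(m, ["T"], "N")

    def test_normalizer_invariance_of_within_sample_ratios(self):
        """Changing normalizer rescales each sample's q by a constant, so
        target/target ratios within a sample are normalizer-invariant."""
        rng = np.random.default_rng(5)
        arr = rng.normal(18, 2, (6, 4))
        m = make_ct(arr, genes=["T1", "T2", "N1", "N2"],
                    gene_role={"T1": "target", "T2": "target"})
        e1 = rs.relative_expression(m, ["T1", "T2"], "N1")
        e2 = rs.relative_expression(m, ["T1", "T2"], "N2")
        np.testing.assert_allclose(
            e1.q["T1"] / e1.q["T2"], e2.q["T1"] / e2.q["T2"], rtol=1e-12
        )


class TestRatioMatrix:
    def test_two_fold_flags(self):
        m = two_gene_matrix([20.0, 20.0 - np.log2(3)], [20.0, 20.0])
        e = rs.relative_expression(m, ["T"], "N")
        rm = rs.ratio_matrix(e, "T")
        s1, s2 = rm.ratios.index
        assert rm.ratios.loc[s1, s2] == pytest.approx(3.0)
        assert rm.flags.loc[s1, s2] == "up"       # column sample vs row
        assert rm.flags.loc[s2, s1] == "down"
        assert (np.diag(rm.ratios) == 1.0).all()

    def test_all_equal_gives_unchanged(self):
        m = two_gene_matrix([20.0] * 4, [18.0] * 4)
        rm = rs.ratio_matrix(rs.relative_expression(m, ["T"], "N"), "T")
        assert (rm.flags == "unchanged").all().all()
        assert rm.flag_count() == 0

    @given(st.lists(st.floats(5.0, 30.0), min_size=2, max_size=8))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_antisymmetry(self, cts):
        m = two_gene_matrix(cts, [15.0] * len(cts))
        rm = rs.ratio_matrix(rs.relative_expression(m, ["T"], "N"), "T")
        prod = rm.ratios.to_numpy() * rm.ratios.to_numpy().T
        np.testing.assert_allclose(prod, 1.0, rtol=1e-9)


class TestArtifactMatrix:
    def test_best_equals_worst_no_flags(self, twelve_sample_matrix):
        d = rs.slice_groups(twelve_sample_matrix, ["BMSC", "ASC"])
        e = rs.relative_expression(d, ["ICAM1"], "ACTB")
        rm = rs.ratio_matrix(e, "ICAM1")
        art = rs.artifact_matrix(rm, rm)
        assert art.flag_count() == 0
        np.testing.assert_allclose(art.modulation, 1.0)

    def test_flag_threshold(self):
        m = two_gene_matrix([20.0, 20.0], [20.0, 20.0])
        e = rs.relative_expression(m, ["T"], "N")
        base = rs.ratio_matrix(e, "T")
        worst = rs.ratio_matrix(e, "T")
        worst.ratios.iloc[0, 1] = 2.5
        art = rs.artifact_matrix(base, worst)
        assert art.modulation.iloc[0, 1] == pytest.approx(2.5)
        assert bool(art.flags.iloc[0, 1])

    def test_mismatched_samples_rejected(self):
        m = two_gene_matrix([20.0] * 4, [18.0] * 4)
        e = rs.relative_expression(m, ["T"], "N")
        a = rs.ratio_matrix(e, "T")
        b = rs.ratio_matrix(e, "T", samples=e.q.index[:3])
        with pytest.raises(rs.ValidationError, match="sample"):
            rs.artifact_matrix(a, b)

    def test_group_shifted_normalizer_flags_all_cross_group_cells(self):
        """Noiseless data, worst normalizer carries a +2-cycle shift in one
        of two groups: every cross-group cell shows 4-fold apparent
        modulation and is flagged; within-group cells are clean."""
        genes = [
            rs.GeneSpec("TGT", 20.0, role="target"),
            rs.GeneSpec("GOOD", 15.0),
            rs.GeneSpec("BAD", 15.0, source_shift={"b": 2.0}),
        ]
        m = rs.generate_ct(rs.StudyDesign(groups=["a", "b"], seed=0), genes)
        d = rs.slice_groups(m, ["a", "b"])
        best = rs.ratio_matrix(rs.relative_expression(d, ["TGT"], "GOOD"), "TGT")
        worst = rs.ratio_matrix(rs.relative_expression(d, ["TGT"], "BAD"), "TGT")
        art = rs.artifact_matrix(best, worst)
        grp = d.meta["group"]
        cross = np.not_equal.outer(grp.to_numpy(), grp.to_numpy())
        assert art.flags.to_numpy()[cross].all()
        assert not art.flags.to_numpy()[~cross].any()


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(0)
        base = rng.normal(20, 0.2, 4)
        cts = np.concatenate([base, base])
        m = two_gene_matrix(cts, [15.0] * 8, groups=["a"] * 4 + ["b"] * 4)
        e = rs.relative_expression(m, ["T"], "N")
        gc = rs.compare_groups(e, "T")
        assert gc.test == "t-test"
        row = gc.pairwise.iloc[0]
        assert row["fold_change"] == pytest.approx(1.0)
        assert not row["significant"]

    def test_three_groups_reports_all_tukey_pairs(self, twelve_sample_matrix):
        d = rs.slice_groups(twelve_sample_matrix, ["BMSC", "ASC", "hAMSC"])
        e = rs.relative_expression(d, ["ICAM1"], "ACTB")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gc = rs.compare_groups(e, "ICAM1")
        assert gc.test == "RM-ANOVA+Tukey"
        assert len(gc.pairwise) == 3
        assert set(map(tuple, gc.pairwise[["group_a", "group_b"]].to_numpy())) == {
            ("BMSC", "ASC"), ("BMSC", "hAMSC"), ("ASC", "hAMSC"),
        }

    def test_unpaired_switch_uses_oneway_anova(self, twelve_sample_matrix):
        d = rs.slice_groups(twelve_sample_matrix, ["BMSC", "ASC", "hAMSC"])
        e = rs.relative_expression(d, ["IL8"], "TBP")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gc = rs.compare_groups(e, "IL8", paired=False)
        assert gc.test == "ANOVA+Tukey"

    def test_dual_threshold_verdict_requires_both(self):
        # large fold change but tiny samples with huge spread -> p >= 0.05
        m = two_gene_matrix(
            [20.0, 26.0, 14.0, 19.0, 25.0, 13.0], [15.0] * 6,
            groups=["a"] * 3 + ["b"] * 3,
        )
        e = rs.relative_expression(m, ["T"], "N")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gc = rs.compare_groups(e, "T")
        row = gc.pairwise.iloc[0]
        assert not row["significant"] or (
            row["p_value"] < 0.05 and row["fold_change"] > 2
        )

    def test_strong_group_shift_detected(self):
        """IL8-like −8-cycle source shift: significant with fold change well
        above 100 in nearly all seeds (power check at reduced seed count)."""
        hits = 0
        n = 40
        for seed in range(n):
            genes = [
                rs.GeneSpec("N", 15.0, noise_sd=0.1),
                rs.GeneSpec("IL8", 22.0, source_shift={"b": -8.0},
                            noise_sd=0.3, role="target"),
            ]
            m = rs.generate_ct(rs.StudyDesign(groups=["a", "b"], seed=seed), genes)
            e = rs.relative_expression(rs.slice_groups(m, ["a", "b"]), ["IL8"], "N")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gc = rs.compare_groups(e, "IL8")
            row = gc.pairwise.iloc[0]
            hits += bool(row["significant"] and row["fold_change"] > 100)
        assert hits / n >= 0.95
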