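import itertools

import numpy as np
import pandas as pd
import pytest

import refstab as rs

from conftest import make_ct


def brute_force_m(x: pd.DataFrame, ddof=1) -> dict:
    """Independent enumeration of all pairwise SDs and their means."""
    return {
        g: np.mean(
            [np.std(x[g] - x[k], ddof=ddof) for k in x.columns if k != g]
        )
        for g in x.columns
    }


class TestGeNorm:
    def test_constant_ct_difference_gives_zero_m(self):
        m = make_ct([[10, 12], [11, 13], [12, 14], [13, 15]])
        t = rs.genorm(m)
        np.testing.assert_allclose(t.values, 0.0, atol=1e-12)

    def test_matches_brute_force_oracle(self, small_matrix):
        t = rs.genorm(small_matrix)
        expected = brute_force_m(small_matrix.values)
        for g in small_matrix.genes:
            assert t.values[g] == pytest.approx(expected[g], abs=1e-12)

    def test_invariant_to_per_sample_offset(self, small_matrix):
        t1 = rs.genorm(small_matrix)
        shifted = small_matrix.values.copy()
        shifted.iloc[0] += 0.7  # whole sample moved by a global offset
        m2 = make_ct(shifted.to_numpy(), genes=small_matrix.genes)
        t2 = rs.genorm(m2)
        np.testing.assert_allclose(t1.values, t2.values, atol=1e-12)

    def test_best_pair_members_in_gene_list(self, twelve_sample_matrix):
        t = rs.genorm(twelve_sample_matrix, twelve_sample_matrix.hkgs)
        assert set(t.extras["best_pair"]) <= set(twelve_sample_matrix.hkgs)
        assert len(t.extras["exclusion_order"]) == 3

    def test_fewer_than_two_genes_rejected(self, small_matrix):
        with pytest.raises(rs.ValidationError):
            rs.genorm(small_matrix, ["A"])

    def test_greedy_exclusion_order_from_brute_force(self):
        """The exclusion path replicates a hand-executed greedy pass."""
        rng = np.random.default_rng(11)
        x = pd.DataFrame(rng.normal(15, 1, (12, 5)), columns=list("ABCDE"))
        t = rs.genorm(make_ct(x.to_numpy(), genes=list(x.columns)))
        genes = list(x.columns)
        order = []
        while len(genes) > 2:
            m = brute_force_m(x[genes])
            worst = max(genes, key=lambda g: (m[g], genes.index(g)))
            order.append(worst)
            genes.remove(worst)
        assert t.extras["exclusion_order"] == order
        assert set(t.extras["best_pair"]) == set(genes)


class TestDeltaCt:
    def test_identical_to_genorm_full_panel(self, twelve_sample_matrix):
        """Before exclusion, the two definitions are the same statistic."""
        hkgs = twelve_sample_matrix.hkgs
        gn = rs.genorm(twelve_sample_matrix, hkgs)
        dc = rs.delta_ct_method(twelve_sample_matrix, hkgs)
        np.testing.assert_allclose(gn.values, dc.values, atol=1e-12)

    def test_matches_brute_force_on_five_genes(self):
        rng = np.random.default_rng(3)
        x = pd.DataFrame(rng.normal(14, 1.2, (10, 5)), columns=list("ABCDE"))
        t = rs.delta_ct_method(make_ct(x.to_numpy(), genes=list(x.columns)))
        expected = brute_force_m(x)
        for g in x.columns:
            assert t.values[g] == pytest.approx(expected[g], abs=1e-12)

    def test_group_shifted_gene_scores_worst(self):
        m = rs.generate_ct(
            rs.StudyDesign(seed=21),
            [
                rs.GeneSpec("A", 12.0, noise_sd=0.2),
                rs.GeneSpec("B", 13.0, noise_sd=0.2),
                rs.GeneSpec("S", 14.0, source_shift={"ASC": 3.0}, noise_sd=0.2),
                rs.GeneSpec("C", 15.0, noise_sd=0.2),
            ],
        )
        t = rs.delta_ct_method(m)
        assert t.values.idxmax() == "S"


class TestBestKeeper:
    def test_constant_gene_has_zero_sd_and_rank_one(self):
        m = make_ct([[10, 12.3], [10, 11.1], [10, 13.2]])
        t = rs.bestkeeper(m)
        assert t.values["G1"] == 0.0
        assert rs.rank_method(t).ranks["G1"] == 1

    def test_sd_formula_divisor_n(self):
        m = make_ct([[10, 11], [12, 11.5], [14, 12]])
        t = rs.bestkeeper(m)
        # population SD of (10, 12, 14) about mean 12: sqrt(8/3)
        assert t.values["G1"] == pytest.approx(np.sqrt(8.0 / 3.0), abs=1e-12)

    def test_not_invariant_to_per_sample_offset(self, small_matrix):
        t1 = rs.bestkeeper(small_matrix)
        shifted = small_matrix.values + np.array([[1.0], [0.0], [-1.0], [0.0]])
        t2 = rs.bestkeeper(make_ct(shifted.to_numpy(), genes=small_matrix.genes))
        assert not np.allclose(t1.values, t2.values)

    def test_pearson_r_against_geometric_mean_index(self, small_matrix):
        t = rs.bestkeeper(small_matrix)
        x = small_matrix.values
        idx = np.exp(np.log(x).mean(axis=1))
        for g in small_matrix.genes:
            assert t.extras["pearson_r"][g] == pytest.approx(
                np.corrcoef(x[g], idx)[0, 1], abs=1e-12
            )


class TestNormFinder:
    def test_constant_matrix_gives_zero_stability(self):
        m = make_ct(np.full((6, 4), 15.0), groups=["a"] * 3 + ["b"] * 3)
        t = rs.normfinder(m)
        np.testing.assert_allclose(t.values, 0.0, atol=1e-12)

    def test_group_shifted_gene_scores_worst(self):
        wins = 0
        for seed in range(30):
            m = rs.generate_ct(
                rs.StudyDesign(groups=["a", "b"], seed=seed),
                [
                    rs.GeneSpec("A", 12.0, noise_sd=0.2),
                    rs.GeneSpec("X", 13.0, source_shift={"b": 1.5}, noise_sd=0.2),
                    rs.GeneSpec("B", 14.0, noise_sd=0.2),
                    rs.GeneSpec("C", 15.0, noise_sd=0.2),
                ],
            )
            wins += rs.normfinder(m).values.idxmax() == "X"
        assert wins >= 28

    def test_ungrouped_tracks_generating_noise(self):
        """Single-group stability values estimate the true per-gene noise
        SDs: ensemble means recover (0.1, 0.2, 0.4) and the well-separated
        pair orders correctly in almost every run.  With 12 samples the
        adjacent 0.1-vs-0.2 pair is only majority-ordered per seed — the
        estimator is unbiased but noisy at that n."""
        genes = [
            rs.GeneSpec("lo", 12.0, noise_sd=0.1),
            rs.GeneSpec("mid", 14.0, noise_sd=0.2),
            rs.GeneSpec("hi", 16.0, noise_sd=0.4),
        ]
        n = 100
        vals, lo_hi, strict = [], 0, 0
        for seed in range(n):
            m = rs.generate_ct(
                rs.StudyDesign(groups=["g"], donors_per_group=12, seed=seed), genes
            )
            v = rs.normfinder(m).values
            vals.append(v)
            lo_hi += bool(v["lo"] < v["hi"])
            strict += bool(v["lo"] < v["mid"] < v["hi"])
        means = pd.DataFrame(vals).mean()
        np.testing.assert_allclose(
            means[["lo", "mid", "hi"]], [0.1, 0.2, 0.4], rtol=0.2
        )
        assert lo_hi / n >= 0.95
        assert strict / n >= 0.6

    def test_group_of_one_rejected(self):
        m = make_ct(np.arange(12.0).reshape(4, 3), groups=["a", "a", "a", "b"])
        with pytest.raises(rs.ValidationError, match="size 1"):
            rs.normfinder(m)

    def test_two_genes_warns(self, small_matrix):
        with pytest.warns(UserWarning, match="fewer than 3"):
            rs.normfinder(small_matrix, ["A", "B"])


class TestSharedProperties:
    def test_run_all_methods_order_and_shape(self, twelve_sample_matrix):
        d = rs.slice_groups(twelve_sample_matrix, ["BMSC", "ASC", "hAMSC"])
        tables = rs.run_all_methods(d, twelve_sample_matrix.hkgs)
        assert [t.method for t in tables] == [
            "DeltaCt", "BestKeeper", "NormFinder", "geNorm",
        ]
        for t in tables:
            assert len(t.values) == 5
            assert (t.values >= 0).all()

    def test_single_group_slice_dispatches_ungrouped_normfinder(
        self, twelve_sample_matrix
    ):
        d = rs.slice_groups(twelve_sample_matrix, ["BMSC"])
        t = rs.normfinder(d, twelve_sample_matrix.hkgs)
        assert t.extras["grouped"] is False

    @pytest.mark.parametrize("method", [rs.genorm, rs.delta_ct_method,
                                        rs.bestkeeper, rs.normfinder])
    def test_permutation_equivariance(self, twelve_sample_matrix, method):
        hkgs = twelve_sample_matrix.hkgs
        t1 = method(twelve_sample_matrix, hkgs)
        t2 = method(twelve_sample_matrix, hkgs[::-1])
        np.testing.assert_allclose(
            t1.values.loc[hkgs], t2.values.loc[hkgs], atol=1e-12
        )

    def test_sample_duplication_invariance_divisor_n(self, small_matrix):
        """Duplicating every sample leaves the pairwise statistics unchanged
        under the divisor-n convention."""
        x = small_matrix.values
        doubled = make_ct(
            np.repeat(x.to_numpy(), 2, axis=0), genes=small_matrix.genes
        )
        for fn in (rs.genorm, rs.delta_ct_method):
            t1 = fn(small_matrix, ddof=0)
            t2 = fn(doubled, ddof=0)
            np.testing.assert_allclose(t1.values, t2.values, atol=1e-12)

    def test_missing_value_fails_loudly(self, twelve_sample_matrix):
        vals = twelve_sample_matrix.values.copy()
        vals.iloc[2, 1] = np.nan
        m = make_ct(
            vals.to_numpy(),
            genes=twelve_sample_matrix.genes,
            groups=[s.group for s in twelve_sample_matrix.samples],
            donors=[s.donor for s in twelve_sample_matrix.samples],
        )
        with pytest.raises(rs.ValidationError, match="missing"):
            rs.delta_ct_method(m, m.genes[:5])
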