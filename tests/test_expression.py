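import numpy as np
import pandas as pd
import pytest

from bambuseq.expression import (
    CountMatrix,
    ExpressionMatrix,
    apply_thresholds,
    bootstrap_replicate_qc,
    correlation_distance,
    de_test,
    delta_ct,
    enrich,
    filter_low,
    fpkm,
    hcluster_cut,
    linkage_to_newick,
    log2_fpkm,
    mad_select,
    subset,
)
from bambuseq.synthetic import CountDesign, simulate_counts


def make_cm(counts, lengths=None):
    counts = np.asarray(counts)
    return CountMatrix(
        genes=[f"g{i}" for i in range(counts.shape[0])],
        libraries=[f"l{j}" for j in range(counts.shape[1])],
        counts=counts,
        lengths=lengths,
    )


class TestFpkm:
    def test_formula_hand_case(self):
        # count 10, length 1000, library total 1e6 -> FPKM 10
        counts = np.zeros((2, 1), int)
        counts[0, 0] = 10
        counts[1, 0] = 10**6 - 10
        cm = make_cm(counts, lengths=np.array([1000.0, 500.0]))
        em = fpkm(cm)
        assert em.values[0, 0] == pytest.approx(10.0)

    def test_zero_count_gives_zero(self):
        cm = make_cm([[0, 5], [10, 5]], lengths=np.array([100.0, 100.0]))
        assert fpkm(cm).values[0, 0] == 0.0

    def test_matches_cellwise_recomputation(self, rng):
        counts = rng.integers(0, 200, (20, 4))
        counts[0] += 1  # avoid zero library totals
        lengths = rng.integers(200, 3000, 20).astype(float)
        cm = make_cm(counts, lengths=lengths)
        em = fpkm(cm)
        totals = counts.sum(axis=0)
        for i in range(20):
            for j in range(4):
                expected = counts[i, j] * 1e9 / (lengths[i] * totals[j])
                assert em.values[i, j] == pytest.approx(expected)

    def test_depth_invariance(self, rng):
        counts = rng.integers(1, 100, (10, 3))
        lengths = rng.integers(200, 2000, 10).astype(float)
        a = fpkm(make_cm(counts, lengths=lengths))
        b = fpkm(make_cm(counts * 7, lengths=lengths))
        assert np.allclose(a.values, b.values)

    def test_library_fpkm_length_sum_is_one(self, rng):
        counts = rng.integers(1, 100, (10, 3))
        lengths = rng.integers(200, 2000, 10).astype(float)
        em = fpkm(make_cm(counts, lengths=lengths))
        sums = (em.values * lengths[:, None] / 1e9).sum(axis=0)
        assert np.allclose(sums, 1.0)

    def test_zero_total_library_named(self):
        cm = make_cm([[0, 5]], lengths=np.array([100.0]))
        with pytest.raises(ValueError, match="l0"):
            fpkm(cm)

    def test_log2_is_nonnegative(self, rng):
        counts = rng.integers(0, 50, (10, 3))
        counts[0] += 1
        em = log2_fpkm(make_cm(counts, lengths=np.full(10, 500.0)))
        assert em.scale == "log2fpkm" and (em.values >= 0).all()


class TestFilterLow:
    def test_mean_threshold_boundary(self):
        cm = make_cm([[0, 1], [1, 1], [2, 2]])  # means 0.5, 1.0, 2.0
        kept = filter_low(cm, 1.0)
        assert kept.genes == ["g1", "g2"]

    def test_all_zero_matrix(self):
        assert filter_low(make_cm(np.zeros((4, 3), int))).genes == []

    def test_zero_threshold_is_identity(self):
        cm = make_cm([[0, 0], [5, 5]])
        assert filter_low(cm, 0).genes == cm.genes


class TestMadSelect:
    def test_varying_gene_beats_constant_gene(self):
        em = ExpressionMatrix(["flat", "wave"], list("abcd"),
                              np.array([[3.0, 3, 3, 3], [0.0, 5, 1, 6]]), "log2fpkm")
        assert mad_select(em, 1) == ["wave"]

    def test_unscaled_mad_hand_case(self):
        vals = np.array([[1.0, 2, 3, 4, 5]])
        med = np.median(vals)
        assert np.median(np.abs(vals - med)) == 1.0
        em = ExpressionMatrix(["g"], list("abcde"), vals, "log2fpkm")
        assert mad_select(em, 1) == ["g"]

    def test_top_n_all_is_identity_set(self, rng):
        vals = rng.normal(size=(10, 4))
        em = ExpressionMatrix([f"g{i}" for i in range(10)], list("abcd"),
                              vals, "log2fpkm")
        assert set(mad_select(em, 10)) == set(em.genes)

    def test_top_n_too_large_warns_and_returns_all(self, rng):
        em = ExpressionMatrix(["g0", "g1"], list("abc"),
                              rng.normal(size=(2, 3)), "log2fpkm")
        with pytest.warns(UserWarning):
            assert len(mad_select(em, 5)) == 2


class TestCorrelationDistance:
    def test_identical_profiles_distance_zero(self):
        v = np.array([[1.0, 2, 3], [2.0, 4, 6]])  # perfectly correlated
        d = correlation_distance(v, ["a", "b"])
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_negated_profile_distance_two(self):
        v = np.array([[1.0, 2, 3], [-1.0, -2, -3]])
        d = correlation_distance(v, ["a", "b"])
        assert d[0, 1] == pytest.approx(2.0)

    def test_constructed_half_correlation(self):
        z1 = np.array([1.0, -1, 1, -1])
        z2 = np.array([1.0, 1, -1, -1])  # orthogonal, equal norm, zero mean
        y = 0.5 * z1 + np.sqrt(0.75) * z2
        d = correlation_distance(np.vstack([z1, y]), ["x", "y"])
        assert d[0, 1] == pytest.approx(0.5)

    def test_affine_invariance_positive_slope(self, rng):
        v = rng.normal(size=(4, 6))
        d1 = correlation_distance(v, list("abcd"))
        d2 = correlation_distance(3.0 * v + 11.0, list("abcd"))
        assert np.allclose(d1, d2)

    def test_constant_profile_named_in_error(self):
        v = np.array([[1.0, 1, 1], [0.0, 1, 2]])
        with pytest.raises(ValueError, match="flatgene"):
            correlation_distance(v, ["flatgene", "g"])


class TestHcluster:
    def test_k_one_single_cluster(self, rng):
        v = rng.normal(size=(6, 5))
        d = correlation_distance(v, [f"g{i}" for i in range(6)])
        cr = hcluster_cut(d, [f"g{i}" for i in range(6)], 1)
        assert set(cr.assignments.values()) == {1}

    def test_two_well_separated_archetypes_perfectly_recovered(self, rng):
        from sklearn.metrics import adjusted_rand_score

        up = np.array([1.0, 1, 5, 5, 1, 1])
        down = np.array([5.0, 5, 1, 1, 5, 5])
        vals, truth = [], []
        for i in range(20):
            base = up if i % 2 == 0 else down
            vals.append(base + rng.normal(0, 0.05, 6))
            truth.append(i % 2)
        ids = [f"g{i}" for i in range(20)]
        d = correlation_distance(np.array(vals), ids)
        cr = hcluster_cut(d, ids, 2)
        assert adjusted_rand_score(truth, [cr.assignments[g] for g in ids]) == 1.0

    def test_k_too_large_rejected(self, rng):
        v = rng.normal(size=(3, 4))
        d = correlation_distance(v, list("abc"))
        with pytest.raises(ValueError):
            hcluster_cut(d, list("abc"), 5)

    def test_newick_export_contains_all_leaves(self, rng):
        ids = [f"g{i}" for i in range(5)]
        d = correlation_distance(rng.normal(size=(5, 4)), ids)
        cr = hcluster_cut(d, ids, 2)
        nwk = linkage_to_newick(cr.linkage, ids)
        assert nwk.endswith(";") and all(g in nwk for g in ids)


class TestBootstrapQc:
    def test_coherent_replicates_not_flagged(self):
        cm, truth = simulate_counts(CountDesign(n_genes=800), seed=11)
        em = log2_fpkm(filter_low(cm))
        res = bootstrap_replicate_qc(em, truth.library_tissue, n_boot=200, seed=1)
        assert res.flagged == []

    def test_injected_outlier_flagged_exactly(self):
        design = CountDesign(n_genes=800, outlier_libraries=("ShA_R2",))
        cm, truth = simulate_counts(design, seed=12)
        em = log2_fpkm(filter_low(cm))
        res = bootstrap_replicate_qc(em, truth.library_tissue, n_boot=200, seed=2)
        assert res.flagged == ["ShA_R2"]

    def test_zero_bootstraps_rejected(self):
        cm, truth = simulate_counts(CountDesign(n_genes=100), seed=13)
        em = log2_fpkm(cm)
        with pytest.raises(ValueError):
            bootstrap_replicate_qc(em, truth.library_tissue, n_boot=0)

    def test_singleton_group_rejected(self):
        cm, truth = simulate_counts(CountDesign(n_genes=100), seed=14)
        em = log2_fpkm(cm)
        groups = dict(truth.library_tissue)
        groups["Cb_R1"] = "lonely"
        with pytest.raises(ValueError, match="lonely"):
            bootstrap_replicate_qc(em, groups, n_boot=100)


class TestDeTest:
    def test_copied_columns_give_zero_log2fc(self, rng):
        counts = rng.integers(0, 300, (50, 3))
        cm = make_cm(np.hstack([counts, counts]))
        de = de_test(cm, ["l0", "l1", "l2"], ["l3", "l4", "l5"])
        assert np.allclose(de["log2fc"], 0.0)

    def test_all_zero_gene_gets_p_one(self):
        counts = np.vstack([np.zeros(6, int), np.full(6, 50)])
        cm = make_cm(counts)
        de = de_test(cm, ["l0", "l1", "l2"], ["l3", "l4", "l5"])
        assert de.loc["g0", "p"] == 1.0 and de.loc["g0", "log2fc"] == 0.0

    def test_threshold_rule(self):
        de = pd.DataFrame(
            {"log2fc": [2.0, 0.5, -1.5, 3.0], "p": [0.001, 0.001, 0.005, 0.5]},
            index=["a", "b", "c", "d"],
        )
        assert apply_thresholds(de, 0.01, 2.0) == {"a", "c"}

    def test_single_library_group_rejected(self, rng):
        cm = make_cm(rng.integers(0, 50, (10, 4)))
        with pytest.raises(ValueError):
            de_test(cm, ["l0"], ["l1", "l2"])

    def test_adjusted_p_at_least_raw(self, rng):
        counts = rng.integers(0, 300, (100, 6))
        cm = make_cm(counts)
        de = de_test(cm, ["l0", "l1", "l2"], ["l3", "l4", "l5"])
        assert (de["padj"] >= de["p"] - 1e-12).all()


class TestEnrich:
    def test_exact_hand_case(self):
        # N=10, K=5, n=4, k=4 -> 5/210
        bg = [f"g{i}" for i in range(10)]
        term = {"T": bg[:5]}
        res = enrich(bg[:4], term, bg)
        assert res.loc["T", "p"] == pytest.approx(5 / 210)

    def test_term_covering_background_p_one(self):
        bg = [f"g{i}" for i in range(8)]
        res = enrich(bg[:3], {"T": bg}, bg)
        assert res.loc["T", "p"] == pytest.approx(1.0)

    def test_zero_hits_p_one(self):
        bg = [f"g{i}" for i in range(8)]
        res = enrich(bg[:3], {"T": bg[5:]}, bg)
        assert res.loc["T", "p"] == pytest.approx(1.0)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            enrich([], {"T": []}, [])

    def test_gene_set_outside_background_rejected(self):
        with pytest.raises(ValueError):
            enrich(["x"], {"T": ["a"]}, ["a", "b"])


class TestDeltaCt:
    def table(self, rows):
        return pd.DataFrame(rows, columns=["sample", "gene", "ct"])

    def test_target_equal_to_reference_mean_gives_one(self):
        t = self.table([("s1", "ref1", 25.0), ("s1", "tgt", 25.0)])
        out = delta_ct(t, ["ref1"])
        assert out.loc[0, "expression"] == pytest.approx(1.0)

    def test_one_cycle_below_reference_doubles(self):
        t = self.table([("s1", "ref1", 25.0), ("s1", "tgt", 24.0)])
        out = delta_ct(t, ["ref1"])
        assert out.loc[0, "expression"] == pytest.approx(2.0)

    def test_two_references_hand_case(self):
        t = self.table([
            ("s1", "PP2A", 25.0), ("s1", "UBC18", 27.0), ("s1", "tgt", 24.0),
        ])
        out = delta_ct(t, ["PP2A", "UBC18"])
        assert out.loc[0, "delta_ct"] == pytest.approx(-2.0)
        assert out.loc[0, "expression"] == pytest.approx(4.0)

    def test_triplicates_averaged_first(self):
        t = self.table([
            ("s1", "ref1", 24.0), ("s1", "ref1", 26.0), ("s1", "tgt", 24.0),
        ])
        out = delta_ct(t, ["ref1"])
        assert out.loc[0, "expression"] == pytest.approx(2.0)

    def test_missing_reference_names_sample(self):
        t = self.table([("s1", "ref1", 25.0), ("s2", "tgt", 24.0)])
        with pytest.raises(ValueError, match="s2"):
            delta_ct(t, ["ref1"])


class TestSubset:
    def test_subset_reorders_rows(self, rng):
        em = ExpressionMatrix(["a", "b", "c"], ["l1"], rng.normal(size=(3, 1)), "fpkm")
        sub = subset(em, ["c", "a"])
        assert sub.genes == ["c", "a"]
        assert np.allclose(sub.values, em.values[[2, 0]])
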