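import numpy as np
import pandas as pd
import pytest

from chromstate.genome_io import BinnedGenome, Segmentation
from chromstate.state_comparison import (
    StateConfusion,
    aggregate_signal_by_state,
    boxplot_summary,
    build_confusion,
    chromatin_type_fractions,
    classify_states,
    comparison_stats,
    feature_overlap,
    group_te_genes,
)
from chromstate.synthetic import expression_table_with_counts


def make_seg(genome, states, names, condition="c"):
    return Segmentation(genome, condition, {"chr1": np.asarray(states)}, names)


@pytest.fixture
def g4():
    return BinnedGenome((("chr1", 800),), 200)


class TestBuildConfusion:
    def test_hand_count(self, g4):
        a = make_seg(g4, [1, 1, 2, 2], ["S1", "S2"])
        b = make_seg(g4, [1, 2, 2, 2], ["S1", "S2"])
        np.testing.assert_array_equal(build_confusion(a, b).B, [[1, 1], [0, 2]])

    def test_identity_is_diagonal(self, g4):
        a = make_seg(g4, [1, 2, 1, 2], ["S1", "S2"])
        B = build_confusion(a, a).B
        assert B.sum() == 4 and np.diag(B).sum() == 4

    def test_total_is_bin_count(self):
        rng = np.random.default_rng(0)
        g = BinnedGenome((("chr1", 4100),), 200)
        a = make_seg(g, rng.integers(1, 4, g.n_bins("chr1")), ["a", "b", "c"])
        b = make_seg(g, rng.integers(1, 4, g.n_bins("chr1")), ["a", "b", "c"])
        conf = build_confusion(a, b)
        assert conf.total == g.total_bins
        # marginals both recover the bin total
        assert conf.B.sum(axis=0).sum() == conf.B.sum(axis=1).sum() == g.total_bins

    def test_grid_mismatch_rejected(self, g4):
        g2 = BinnedGenome((("chr1", 800),), 100)
        a = make_seg(g4, [1, 1, 2, 2], ["S1", "S2"])
        b = Segmentation(g2, "c", {"chr1": np.ones(8, dtype=int)}, ["S1", "S2"])
        with pytest.raises(ValueError, match="grid"):
            build_confusion(a, b)


class TestComparisonStats:
    def test_printed_formula_hand_evaluation(self):
        conf = StateConfusion(np.array([[6, 2], [1, 11]]), ["S1", "S2"])
        st = comparison_stats(conf)
        assert st.jaccard["S1"] == pytest.approx(6 / 9, abs=1e-12)
        assert st.overlap["S1"] == pytest.approx(6 / 8, abs=1e-12)
        assert st.fold_change["S1"] == pytest.approx(np.log2(7 / 8), abs=1e-12)
        assert st.jaccard["S2"] == pytest.approx(11 / (13 + 12 - 11), abs=1e-12)
        assert st.genome_wide_overlap == pytest.approx(17 / 20, abs=1e-12)

    def test_identity_segmentation(self, g4):
        a = make_seg(g4, [1, 2, 2, 1], ["S1", "S2"])
        st = comparison_stats(build_confusion(a, a))
        assert (st.jaccard == 1.0).all() and (st.overlap == 1.0).all()
        assert (st.fold_change == 0.0).all()
        assert st.genome_wide_overlap == 1.0

    def test_complete_exchange(self):
        conf = StateConfusion(np.array([[0, 5], [5, 0]]), ["S1", "S2"])
        st = comparison_stats(conf)
        assert (st.jaccard == 0.0).all() and (st.overlap == 0.0).all()
        assert (st.fold_change == 0.0).all()  # totals equal

    def test_undefined_states_flagged(self):
        conf = StateConfusion(np.array([[4, 0, 0], [0, 0, 0], [2, 0, 0]]), ["a", "b", "c"])
        st = comparison_stats(conf)
        assert np.isnan(st.jaccard["b"])  # absent from both conditions
        assert "b" in st.undefined
        # state c: absent from condition 2 -> JI/O defined, FC = -inf
        assert st.fold_change["c"] == -np.inf

    def test_trace_matches_per_bin_comparison(self):
        rng = np.random.default_rng(1)
        g = BinnedGenome((("chr1", 10000),), 200)
        sa = rng.integers(1, 5, g.n_bins("chr1"))
        sb = rng.integers(1, 5, g.n_bins("chr1"))
        a = make_seg(g, sa, list("wxyz"))
        b = make_seg(g, sb, list("wxyz"))
        st = comparison_stats(build_confusion(a, b))
        assert st.genome_wide_overlap == pytest.approx((sa == sb).mean(), abs=1e-15)


class TestFeatureOverlap:
    def test_single_gene_full_state(self):
        g = BinnedGenome((("chr1", 1000),), 200)
        seg = make_seg(g, [1] * 5, ["S1"])
        ann = pd.DataFrame(
            [("chr1", 0, 1000, "+", "gene", "g1")],
            columns=["chrom", "start", "end", "strand", "feature_class", "id"],
        )
        prop = feature_overlap(seg, ann, ["gene"], proportions=True)
        assert prop.loc["S1", "gene"] == pytest.approx(1.0)

    def test_half_overlap_bp(self):
        g = BinnedGenome((("chr1", 800),), 200)
        seg = make_seg(g, [1, 1, 2, 2], ["S1", "S2"])
        # S2 covers [400,800); TE gene covers [600,1000) clipped -> 200 bp overlap
        ann = pd.DataFrame(
            [("chr1", 600, 800, "+", "TE gene", "te1")],
            columns=["chrom", "start", "end", "strand", "feature_class", "id"],
        )
        bp = feature_overlap(seg, ann, ["TE gene"])
        assert bp.loc["S2", "TE gene"] == 200
        assert bp.loc["S1", "TE gene"] == 0

    def test_partition_proportions_sum_to_one(self):
        rng = np.random.default_rng(2)
        g = BinnedGenome((("chr1", 20000),), 200)
        seg = make_seg(g, rng.integers(1, 4, g.n_bins("chr1")), ["a", "b", "c"])
        # random non-overlapping partition of the chromosome into two classes
        cuts = np.sort(rng.choice(np.arange(100, 19900), size=10, replace=False))
        bounds = np.concatenate(([0], cuts, [20000]))
        rows = []
        for i, (s, e) in enumerate(zip(bounds[:-1], bounds[1:])):
            rows.append(("chr1", int(s), int(e), "+", "gene" if i % 2 else "TE gene", f"f{i}"))
        ann = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "feature_class", "id"])
        prop = feature_overlap(seg, ann, ["gene", "TE gene"], proportions=True)
        np.testing.assert_allclose(prop.sum(axis=1), 1.0, atol=1e-12)

    def test_matches_per_bp_brute_force(self):
        rng = np.random.default_rng(3)
        g = BinnedGenome((("chr1", 3000),), 200)
        seg = make_seg(g, rng.integers(1, 3, g.n_bins("chr1")), ["a", "b"])
        rows = []
        for i in range(8):
            s = int(rng.integers(0, 2900))
            e = int(rng.integers(s + 1, 3000))
            rows.append(("chr1", s, e, "+", "gene", f"g{i}"))
        ann = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "feature_class", "id"])
        bp = feature_overlap(seg, ann, ["gene"])
        # brute force: per-base membership arrays
        covered = np.zeros(3000, dtype=bool)
        for r in rows:
            covered[r[1]:r[2]] = True
        state_of_base = np.repeat(seg.state_of_bin["chr1"], 200)[:3000]
        for k, name in enumerate(["a", "b"], start=1):
            assert bp.loc[name, "gene"] == int(covered[state_of_base == k].sum())


class TestClassifyStates:
    def test_clear_majority(self):
        fr = pd.DataFrame([{"H": 0.70, "F": 0.15, "E": 0.10, "I": 0.05}], index=["s1"])
        assert classify_states(fr).assignment["s1"] == "H"

    def test_second_type_too_large(self):
        fr = pd.DataFrame([{"H": 0.70, "F": 0.25, "E": 0.05}], index=["s1"])
        assert classify_states(fr).assignment["s1"] == "mixed:H+F"

    def test_strict_inequalities_at_boundaries(self):
        fr = pd.DataFrame([{"H": 0.66, "F": 0.14, "E": 0.20}], index=["s1"])
        assert classify_states(fr).assignment["s1"].startswith("mixed:")

    def test_fraction_validation(self):
        fr = pd.DataFrame([{"H": 1.2, "F": 0.0}], index=["s1"])
        with pytest.raises(ValueError):
            classify_states(fr)

    def test_fractions_from_reference_segmentation(self, g4):
        seg = make_seg(g4, [1, 1, 2, 2], ["s1", "s2"])
        ref = make_seg(g4, [1, 1, 1, 2], ["H1", "F1"])
        fr = chromatin_type_fractions(seg, ref, {"H1": "H", "F1": "F"})
        assert fr.loc["s1", "H"] == 1.0
        assert fr.loc["s2", "H"] == 0.5 and fr.loc["s2", "F"] == 0.5


class TestAggregateSignal:
    def signal(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])

    def test_constant_signal(self):
        g = BinnedGenome((("chr1", 800),), 200)
        seg = make_seg(g, [1, 1, 2, 2], ["S1", "S2"])
        sig = self.signal([("chr1", 0, 800, 0.8)])
        dist = aggregate_signal_by_state(seg, sig)
        for s in ("S1", "S2"):
            np.testing.assert_allclose(dist[s], [0.8])

    def test_bp_weighted_mean_within_region(self):
        g = BinnedGenome((("chr1", 400),), 200)
        seg = make_seg(g, [1, 1], ["S1"])
        sig = self.signal([("chr1", 0, 200, 1.0), ("chr1", 200, 400, 0.0)])
        dist = aggregate_signal_by_state(seg, sig)
        np.testing.assert_allclose(dist["S1"], [0.5])

    def test_matches_per_bin_oracle(self):
        rng = np.random.default_rng(4)
        g = BinnedGenome((("chr1", 10000),), 200)
        states = rng.integers(1, 4, g.n_bins("chr1"))
        seg = make_seg(g, states, ["a", "b", "c"])
        # per-bin signal values (tiling, non-overlapping)
        vals = rng.random(g.n_bins("chr1"))
        starts, ends = g.bin_bounds("chr1")
        sig = self.signal(
            [("chr1", int(s), int(e), float(v)) for s, e, v in zip(starts, ends, vals)]
        )
        dist = aggregate_signal_by_state(seg, sig)
        # oracle: region means computed per state run directly over bins
        iv = seg.to_intervals()
        for name in ("a", "b", "c"):
            expected = []
            for r in iv[iv["state_name"] == name].itertuples(index=False):
                b0, b1 = r.start // 200, -(-r.end // 200)
                w = (ends - starts)[b0:b1]
                expected.append(np.average(vals[b0:b1], weights=w))
            np.testing.assert_allclose(np.sort(dist[name]), np.sort(expected), atol=1e-12)

    def test_region_without_signal_dropped(self):
        g = BinnedGenome((("chr1", 800),), 200)
        seg = make_seg(g, [1, 1, 2, 2], ["S1", "S2"])
        sig = self.signal([("chr1", 0, 400, 1.0)])  # S2's region uncovered
        dist = aggregate_signal_by_state(seg, sig)
        assert dist["S2"].size == 0

    def test_boxplot_summary_tukey_fences(self):
        vals = np.array([1.0, 1.1, 0.9, 1.05, 0.95, 50.0])  # one far outlier
        s = boxplot_summary(vals)
        assert s["high"] <= 1.1 and s["n"] == 5


class TestGroupTEGenes:
    def test_printed_worked_example_counts(self):
        expr, ids = expression_table_with_counts(3901, 497, 2116, seed=0)
        groups = group_te_genes(expr, ids)
        sizes = groups.sizes()
        assert sizes["excluded_wt_expressed"] == 497
        assert sizes["no_expression"] == 2116
        assert sizes["q1"] == sizes["q2"] == sizes["q3"] == sizes["q4"] == 322
        assert len(groups.expressed) == 644

    def test_all_silent(self):
        expr = pd.DataFrame(
            {"wild_type": [0.0, 0.0], "mutant": [0.0, 0.05]},
            index=pd.Index(["a", "b"], name="gene_id"),
        )
        groups = group_te_genes(expr, ["a", "b"])
        assert set(groups.group_of.values()) == {"no_expression"}

    def test_remainder_goes_to_earlier_quartiles(self):
        expr = pd.DataFrame(
            {"wild_type": np.zeros(10), "mutant": np.linspace(1, 10, 10)},
            index=pd.Index([f"t{i}" for i in range(10)], name="gene_id"),
        )
        groups = group_te_genes(expr, list(expr.index))
        sizes = groups.sizes()
        assert [sizes[f"q{i}"] for i in range(1, 5)] == [3, 3, 2, 2]

    def test_quartiles_ordered_by_mutant_tpm(self):
        rng = np.random.default_rng(5)
        tpm = rng.uniform(0.2, 100, 40)
        expr = pd.DataFrame(
            {"wild_type": np.zeros(40), "mutant": tpm},
            index=pd.Index([f"t{i:02d}" for i in range(40)], name="gene_id"),
        )
        groups = group_te_genes(expr, list(expr.index))
        q1 = expr.loc[groups.members("q1"), "mutant"].max()
        q4 = expr.loc[groups.members("q4"), "mutant"].min()
        assert q1 <= q4

    def test_sizes_partition_input(self):
        expr, ids = expression_table_with_counts(101, 13, 40, seed=1)
        groups = group_te_genes(expr, ids)
        assert sum(groups.sizes().values()) == 101

    def test_missing_ids_rejected(self):
        expr, ids = expression_table_with_counts(10, 2, 3, seed=2)
        with pytest.raises(KeyError):
            group_te_genes(expr, ids + ["nope"])
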