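import numpy as np
import dendropy
import pytest

from melith import clonality
from melith.clonality import (
    build_tree,
    classify,
    heterogeneity_enrichment,
    round_half_away,
    summarize_classes,
)
from melith.reference import min_parsimony_cost
from melith.variant_io import PresenceStatus, RegionCallMatrix, SomaticVariant

from conftest import pattern_matrix

REGIONS10 = [f"PT{i}" for i in range(1, 6)] + [f"IT{i}" for i in range(1, 6)]


class TestClassify:
    def test_present_everywhere_is_trunk(self):
        m = pattern_matrix(REGIONS10, [set(REGIONS10)])
        assert classify(m)[0].clonal_class == "trunk"

    def test_four_of_ten_regions_is_branch(self):
        # the CTNNB1 P492S pattern: PT3, PT5, IT3, IT4 only
        m = pattern_matrix(REGIONS10, [{"PT3", "PT5", "IT3", "IT4"}])
        a = classify(m)[0]
        assert a.clonal_class == "branch"
        assert a.region_set == frozenset({"PT3", "PT5", "IT3", "IT4"})

    def test_single_region_is_private(self):
        m = pattern_matrix(REGIONS10, [{"PT4"}])
        assert classify(m)[0].clonal_class == "private"

    def test_indeterminate_cell_does_not_veto_trunk(self):
        m = pattern_matrix(REGIONS10, [set(REGIONS10)])
        m.status[0, 3] = PresenceStatus.INDETERMINATE
        m.alt[0, 3] = 0
        assert classify(m)[0].clonal_class == "trunk"

    def test_fewer_than_two_regions_rejected(self):
        m = pattern_matrix(["R0"], [{"R0"}])
        with pytest.raises(ValueError, match="2 regions"):
            classify(m)

    def test_variant_present_nowhere_rejected(self):
        m = pattern_matrix(["R0", "R1"], [{"R0"}])
        m.status[0, :] = PresenceStatus.ABSENT
        with pytest.raises(ValueError, match="no region"):
            classify(m)

    def test_class_conservation(self, default_case):
        s = summarize_classes(default_case["annotations"])
        assert (
            s["trunk"]["count"] + s["branch"]["count"] + s["private"]["count"]
            == s["total"]["count"]
        )


class TestSummarize:
    def test_case_study_percentages(self):
        ann = (
            [clonality.ClonalAnnotation(i, "trunk", frozenset(REGIONS10), 10)
             for i in range(1774)]
            + [clonality.ClonalAnnotation(i, "branch", frozenset({"PT3", "PT5"}), 10)
               for i in range(1774, 1805)]
            + [clonality.ClonalAnnotation(i, "private", frozenset({"PT4"}), 10)
               for i in range(1805, 1844)]
        )
        s0 = summarize_classes(ann, decimals=0)
        assert s0["trunk"]["percent"] == 96
        s1 = summarize_classes(ann, decimals=1)
        assert s1["heterogeneous"]["percent"] == 3.8
        assert s1["heterogeneous"]["count"] == 70

    def test_all_trunk_degenerate(self):
        ann = [clonality.ClonalAnnotation(i, "trunk", frozenset({"A", "B"}), 2)
               for i in range(5)]
        s = summarize_classes(ann)
        assert (s["trunk"]["percent"], s["branch"]["percent"],
                s["private"]["percent"]) == (100.0, 0.0, 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_classes([])

    @pytest.mark.parametrize("x,decimals,expected", [
        (86.5, 0, 87), (96.2, 0, 96), (3.75, 1, 3.8), (-2.5, 0, -3), (8.96, 0, 9),
    ])
    def test_round_half_away(self, x, decimals, expected):
        assert round_half_away(x, decimals) == expected


class TestBuildTree:
    def test_trunk_only_star(self):
        m = pattern_matrix(["A", "B", "C"], {frozenset("ABC"): 7})
        tree = build_tree(m, classify(m))
        assert tree.edge_counts[frozenset("ABC")] == 7
        assert tree.total_assigned == 7
        assert not tree.homoplasy
        nwk = tree.to_newick()
        assert nwk.endswith("normal;")
        assert "A:0" in nwk

    def test_nested_patterns_make_caterpillar(self):
        pats = {frozenset("ABC"): 5, frozenset("AB"): 3, frozenset("A"): 2}
        m = pattern_matrix(["A", "B", "C"], pats)
        tree = build_tree(m, classify(m))
        assert tree.edge_counts[frozenset("ABC")] == 5
        assert tree.edge_counts[frozenset("AB")] == 3
        assert tree.edge_counts[frozenset("A")] == 2
        # matches the exhaustive parsimony minimum on 3 leaves
        assert tree.parsimony_cost() == min_parsimony_cost(pats, ["A", "B", "C"])

    def test_conflicting_minority_pattern_is_homoplasy(self):
        pats = {frozenset("ABC"): 4, frozenset("AB"): 3, frozenset("BC"): 1}
        m = pattern_matrix(["A", "B", "C"], pats)
        tree = build_tree(m, classify(m))
        assert frozenset("AB") in tree.edge_counts
        homoplasy_patterns = {h[1] for h in tree.homoplasy}
        assert homoplasy_patterns == {frozenset("BC")}
        # brute-force check: cost equals the true 3-leaf minimum
        assert tree.parsimony_cost() == min_parsimony_cost(pats, ["A", "B", "C"])

    def test_branch_lengths_sum_to_variant_count(self, default_case):
        retained, ann = default_case["retained"], default_case["annotations"]
        tree = build_tree(retained, ann)
        assert tree.total_assigned == retained.n_variants

    def test_newick_parses_with_branch_lengths(self):
        pats = {frozenset("ABCD"): 6, frozenset("AB"): 2, frozenset("C"): 1}
        m = pattern_matrix(["A", "B", "C", "D"], pats)
        tree = build_tree(m, classify(m))
        parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        leaves = {l.taxon.label for l in parsed.leaf_node_iter()}
        assert leaves == {"A", "B", "C", "D"}
        lengths = sorted(
            int(e.length) for e in parsed.preorder_edge_iter() if e.length is not None
        )
        assert sum(lengths) == 9

    def test_trunk_display_shortening_is_cosmetic(self):
        m = pattern_matrix(["A", "B"], {frozenset("AB"): 120})
        tree = build_tree(m, classify(m))
        assert ":50" in tree.to_newick(trunk_display_length=50)
        assert tree.edge_counts[frozenset("AB")] == 120

    def test_empty_annotations_rejected(self):
        m = pattern_matrix(["A", "B"], [{"A", "B"}])
        with pytest.raises(ValueError):
            build_tree(m, [])


class TestGreedyVsExhaustive:
    def _instance(self, rng):
        nreg = int(rng.integers(3, 6))
        regions = [f"R{i}" for i in range(nreg)]
        pats = {frozenset(regions): int(rng.integers(20, 60))}
        for _ in range(int(rng.integers(0, 3))):
            size = int(rng.integers(2, nreg))
            s = frozenset(rng.choice(regions, size=size, replace=False))
            if s not in pats and all(s <= t or t <= s or not (s & t) for t in pats):
                pats[s] = int(rng.integers(5, 20))
        for r in regions:
            if rng.random() < 0.8:
                pats[frozenset([r])] = pats.get(frozenset([r]), 0) + int(rng.integers(2, 7))
        for _ in range(int(rng.integers(0, 3))):
            size = int(rng.integers(2, nreg))
            s = frozenset(rng.choice(regions, size=size, replace=False))
            pats[s] = pats.get(s, 0) + 1
        return regions, pats

    def test_never_below_optimum_and_mostly_equal(self):
        rng = np.random.default_rng(42)
        agree = 0
        n_trials = 60
        for _ in range(n_trials):
            regions, pats = self._instance(rng)
            m = pattern_matrix(regions, pats)
            tree = build_tree(m, classify(m))
            greedy = tree.parsimony_cost()
            best = min_parsimony_cost(pats, regions)
            assert greedy >= best
            agree += greedy == best
        assert agree >= 0.9 * n_trials


class TestHeterogeneityEnrichment:
    def test_identical_proportions_give_p_one(self):
        regions = ["PT1", "PT2", "IT1", "IT2"]
        kinds = {"PT1": "PT", "PT2": "PT", "IT1": "IT", "IT2": "IT"}
        pats = {frozenset(regions): 50,
                frozenset({"PT1"}): 5, frozenset({"IT1"}): 5}
        m = pattern_matrix(regions, pats)
        p, table = heterogeneity_enrichment(classify(m), kinds)
        assert p == 1.0

    def test_needs_both_kinds(self):
        m = pattern_matrix(["PT1", "PT2"], {frozenset({"PT1", "PT2"}): 3})
        with pytest.raises(ValueError):
            heterogeneity_enrichment(classify(m), {"PT1": "PT", "PT2": "PT"})

    def test_case_study_shows_no_enrichment(self, default_case):
        kinds = default_case["config"].region_kinds
        retained = default_case["retained"]
        p, _ = heterogeneity_enrichment(
            default_case["annotations"],
            {r: kinds[r] for r in retained.regions},
        )
        assert p > 0.5
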