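"""Feature classification, safety scoring, and rank-sum comparison."""

import math
from itertools import combinations_with_replacement

import pytest
import scipy.stats as st

from polyqprofile.risk import (
    aggregate_scores,
    classify_constraint,
    classify_expression,
    classify_interactions,
    compare_gene_sets,
    rank_sum_compare,
)
from polyqprofile.types import GeneFeatureProfile


def profile(**kwargs):
    defaults = dict(gene_symbol="X", pli=0.5, tissue_class="tissue_enriched")
    defaults.update(kwargs)
    return GeneFeatureProfile(**defaults)


class TestClassifiers:
    @pytest.mark.parametrize("pli,verdict", [(1.0, True), (0.91, True), (0.9, False),
                                             (0.1, False), (None, None)])
    def test_constraint_strict_threshold(self, pli, verdict):
        assert classify_constraint(profile(pli=pli), 0.9) is verdict

    @pytest.mark.parametrize(
        "tissue,verdict",
        [
            ("low_tissue_specificity", True),
            ("tissue_enhanced", False),
            ("tissue_enriched", False),
            ("not_detected", False),
            (None, None),
        ],
    )
    def test_expression_unfavorable_only_when_broad(self, tissue, verdict):
        assert classify_expression(profile(tissue_class=tissue)) is verdict

    def test_interactions_boundary_just_above_ten(self):
        p = profile(interactions=tuple((f"P{i}", 0.5) for i in range(11)))
        assert classify_interactions(p) == (True, 11)

    def test_interactions_exactly_ten_is_favorable(self):
        p = profile(interactions=tuple((f"P{i}", 0.5) for i in range(10)))
        assert classify_interactions(p) == (False, 10)

    def test_low_confidence_partners_do_not_count(self):
        p = profile(interactions=tuple((f"P{i}", 0.40) for i in range(50)))
        assert classify_interactions(p) == (False, 0)

    def test_mi_exactly_at_cutoff_does_not_count(self):
        p = profile(interactions=(("P1", 0.42),))
        assert classify_interactions(p) == (False, 0)

    def test_fixture_gene_profiles(self, results):
        _, profiles, _ = results
        by_gene = {p.gene_symbol: p for p in profiles}
        assert classify_expression(by_gene["AR"]) is False  # tissue enhanced
        assert classify_expression(by_gene["CACNA1A"]) is False  # tissue enriched
        assert classify_expression(by_gene["HTT"]) is True
        verdict, count = classify_interactions(by_gene["THAP11"])
        assert verdict is False and count <= 10


class TestAggregate:
    def test_fixture_scores(self, results):
        _, profiles, _ = results
        verdicts = aggregate_scores(profiles)
        scores = {v.gene_symbol: v.safety_score for v in verdicts}
        for gene in ("ATN1", "ATXN1", "ATXN7", "HTT"):
            assert scores[gene] == 3
        assert all(s >= 1 for s in scores.values())
        assert round(sum(scores.values()) / len(scores), 1) == 2.2

    def test_all_favorable_gene_scores_zero(self):
        v, = aggregate_scores([profile()])
        assert v.safety_score == 0

    def test_unknown_feature_never_contributes(self):
        v, = aggregate_scores([profile(pli=None, tissue_class=None)])
        assert v.safety_score == 0
        assert v.constraint_unfavorable is None

    def test_ranking_descending_score_then_symbol(self, results):
        _, profiles, _ = results
        verdicts = aggregate_scores(profiles)
        keys = [(-v.safety_score, v.gene_symbol) for v in verdicts]
        assert keys == sorted(keys)

    def test_score_monotone_in_each_feature(self):
        base = profile(pli=0.5, tissue_class="tissue_enriched")
        flipped = [
            profile(pli=0.95, tissue_class="tissue_enriched"),
            profile(pli=0.5, tissue_class="low_tissue_specificity"),
            profile(pli=0.5, interactions=tuple((f"P{i}", 0.5) for i in range(11))),
        ]
        base_score = aggregate_scores([base])[0].safety_score
        for p in flipped:
            assert aggregate_scores([p])[0].safety_score == base_score + 1

    def test_druggable_any_not_in_score(self, results):
        _, profiles, _ = results
        druggable = {p.gene_symbol for p in profiles if p.druggable_evidence}
        assert len(druggable) == 5
        verdicts = aggregate_scores(profiles)
        for v in verdicts:
            assert v.druggable_any == (v.gene_symbol in druggable)


class TestRankSum:
    def test_degenerate_identical_groups(self):
        r = rank_sum_compare([1, 1, 1], [1, 1, 1])
        assert (r.z_value, r.p_two_sided, r.effect_r) == (0.0, 1.0, 0.0)
        assert r.effect_label == "negligible"

    def test_exact_two_vs_two(self):
        r = rank_sum_compare([1, 2], [3, 4], method="exact_enumeration")
        assert r.p_two_sided == pytest.approx(1 / 3)

    def test_exact_disjoint_triples(self):
        r = rank_sum_compare([3, 3, 3], [0, 0, 0], method="exact_enumeration")
        assert r.p_two_sided == pytest.approx(0.1)

    def test_normal_matches_scipy_tie_corrected(self):
        a, b = [3, 3, 3, 3, 2, 2, 2, 2, 1, 1], [1, 1, 1, 1, 1, 1, 0, 0, 3]
        mine = rank_sum_compare(a, b)
        ref = st.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                              use_continuity=False)
        assert mine.u_statistic == ref.statistic
        assert mine.p_two_sided == pytest.approx(ref.pvalue)
        assert mine.effect_r == pytest.approx(abs(mine.z_value) / math.sqrt(19))

    def test_symmetry_negates_z_preserves_p_and_r(self):
        a, b = [3, 2, 2, 1], [1, 1, 0]
        fwd, rev = rank_sum_compare(a, b), rank_sum_compare(b, a)
        assert rev.z_value == pytest.approx(-fwd.z_value)
        assert rev.p_two_sided == pytest.approx(fwd.p_two_sided)
        assert rev.effect_r == pytest.approx(fwd.effect_r)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            rank_sum_compare([], [1])

    def test_effect_r_invariant_under_monotone_relabeling(self):
        a, b = [0, 1, 1, 2], [2, 3, 3]
        mapped = {0: 10, 1: 20, 2: 40, 3: 80}
        r1 = rank_sum_compare(a, b)
        r2 = rank_sum_compare([mapped[x] for x in a], [mapped[x] for x in b])
        assert r1.effect_r == pytest.approx(r2.effect_r)
        assert r1.p_two_sided == pytest.approx(r2.p_two_sided)

    @pytest.mark.parametrize("labels,r_values", [
        (("negligible", "small", "medium", "large"), (0.05, 0.15, 0.35, 0.6)),
    ])
    def test_effect_labels(self, labels, r_values):
        # construct the label directly from the classifier boundaries
        from polyqprofile.risk import _effect_label

        assert tuple(_effect_label(r) for r in r_values) == labels

    def test_normal_approaches_exact_as_groups_grow(self):
        # mean |p_exact - p_normal| shrinks from tiny to moderate group sizes
        def mean_gap(size):
            gaps = []
            for a in combinations_with_replacement(range(4), size):
                for b in combinations_with_replacement(range(4), size):
                    e = rank_sum_compare(list(a), list(b), "exact_enumeration").p_two_sided
                    n = rank_sum_compare(list(a), list(b)).p_two_sided
                    gaps.append(abs(e - n))
            return sum(gaps) / len(gaps)

        assert mean_gap(5) < mean_gap(2)


class TestCompareGeneSets:
    def test_fixture_mean_is_2_2(self, results):
        _, profiles, _ = results
        result, verdicts, _ = compare_gene_sets(profiles, profiles)
        assert result.mean_a == 2.2 and result.n_a == 10

    def test_identical_sets_give_p_one(self, results):
        _, profiles, _ = results
        result, _, _ = compare_gene_sets(profiles, profiles)
        assert result.p_two_sided == pytest.approx(1.0)
        assert result.z_value == pytest.approx(0.0)

    def test_group_means_reported_to_one_decimal(self, results):
        _, profiles, _ = results
        result, _, _ = compare_gene_sets(profiles, profiles[:3])
        assert result.mean_a == round(result.mean_a, 1)
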