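"""Greedy LD pruning, trait assignment, and consequence severity."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyqprofile.ld import assign_traits, prune_catalog, prune_to_haplotypes
from polyqprofile.severity import DEFAULT_SEVERITY, SeverityTable, most_severe
from polyqprofile.types import LDMatrix

from conftest import make_record


def matrix(ids, pairs):
    """LDMatrix from a {(a, b): r2} dict; unlisted pairs get r2 = 0."""
    n = len(ids)
    idx = {v: i for i, v in enumerate(ids)}
    r2 = np.zeros((n, n))
    np.fill_diagonal(r2, 1.0)
    for (a, b), val in pairs.items():
        r2[idx[a], idx[b]] = r2[idx[b], idx[a]] = val
    return LDMatrix(ids, r2)


def brute_force_greedy(variants, pair_r2, cutoff):
    """Independent restatement of the documented greedy tag rule."""
    ordered = sorted(variants, key=lambda v: (v[1], v[2], v[0]))
    assigned, out = set(), []
    for tag, _, _ in ordered:
        if tag in assigned:
            continue
        members = [tag]
        assigned.add(tag)
        for v, _, _ in ordered:
            if v not in assigned and pair_r2.get(frozenset((tag, v)), 0.0) > cutoff:
                members.append(v)
                assigned.add(v)
        out.append((tag, tuple(members)))
    return sorted(out)


class TestPruning:
    def test_single_variant_is_its_own_tag(self):
        ld = matrix(["a"], {})
        [h] = prune_to_haplotypes([("a", 10, 1e-8)], ld, 0.5)
        assert h.tag_variant == "a" and h.member_variants == ("a",)

    def test_complete_ld_collapses_to_one_haplotype(self):
        ids = ["a", "b", "c", "d"]
        ld = matrix(ids, {(x, y): 0.9 for x, y in itertools.combinations(ids, 2)})
        [h] = prune_to_haplotypes([(v, i, 1e-8) for i, v in enumerate(ids, 1)], ld, 0.5)
        assert set(h.member_variants) == set(ids)

    def test_chain_ld_differs_from_single_linkage(self):
        # a-b and b-c in LD but a-c not: greedy from the 5'-most variant (a)
        # absorbs b, leaving c alone; single-linkage would merge all three
        ld = matrix(["a", "b", "c"], {("a", "b"): 0.9, ("b", "c"): 0.9, ("a", "c"): 0.1})
        haps = prune_to_haplotypes([("a", 1, 1e-8), ("b", 2, 1e-8), ("c", 3, 1e-8)], ld, 0.5)
        assert [(h.tag_variant, set(h.member_variants)) for h in haps] == [
            ("a", {"a", "b"}),
            ("c", {"c"}),
        ]

    def test_boundary_r2_does_not_join(self):
        ld = matrix(["a", "b"], {("a", "b"): 0.5})
        haps = prune_to_haplotypes([("a", 1, 1e-8), ("b", 2, 1e-8)], ld, 0.5)
        assert len(haps) == 2

    def test_missing_ld_treated_as_independent(self, caplog):
        r2 = np.array([[1.0, np.nan], [np.nan, 1.0]])
        ld = LDMatrix(["a", "b"], r2)
        with caplog.at_level("WARNING", logger="polyqprofile.ld"):
            haps = prune_to_haplotypes([("a", 1, 1e-8), ("b", 2, 1e-8)], ld, 0.5)
        assert len(haps) == 2
        assert any("missing" in m for m in caplog.messages)

    def test_variant_absent_from_ld_is_an_error(self):
        ld = matrix(["a"], {})
        with pytest.raises(ValueError, match="absent"):
            prune_to_haplotypes([("a", 1, 1e-8), ("z", 2, 1e-8)], ld, 0.5)

    def test_table1_fixture_recovers_published_structure(self, table1):
        records, _, ld = table1
        haps = prune_catalog(records, ld, 0.5)
        assert len(haps) == 21
        per_gene = {}
        for h in haps:
            per_gene[h.gene_symbol] = per_gene.get(h.gene_symbol, 0) + 1
        assert per_gene == {"ATXN1": 8, "HTT": 6, "ATXN7": 3, "ATXN2": 2, "CACNA1A": 2}
        # published tag variants are recovered
        tags = {h.tag_variant for h in haps}
        assert {"rs909788", "rs61348208", "rs9367926", "rs7770062", "rs362307"} <= tags

    def test_haplotype_indices_follow_tag_position(self, table1):
        records, _, ld = table1
        haps = prune_catalog(records, ld, 0.5)
        atxn1 = [h for h in haps if h.gene_symbol == "ATXN1"]
        assert [h.haplotype_index for h in atxn1] == list(range(1, 9))
        assert atxn1[0].tag_variant == "rs719316"

    def test_within_and_across_ld_invariants(self, table1):
        records, _, ld = table1
        haps = prune_catalog(records, ld, 0.5)
        for gene, mat in ld.items():
            gene_haps = [h for h in haps if h.gene_symbol == gene]
            for h in gene_haps:
                for member in h.member_variants:
                    assert mat.get(h.tag_variant, member) > 0.5 or member == h.tag_variant
            for h1, h2 in itertools.combinations(gene_haps, 2):
                assert mat.get(h1.tag_variant, h2.tag_variant) <= 0.5

    @given(st.permutations(range(5)))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_invariant_to_input_row_order(self, perm):
        ids = ["a", "b", "c", "d", "e"]
        ld = matrix(ids, {("a", "b"): 0.9, ("c", "d"): 0.7, ("d", "e"): 0.6})
        variants = [(v, i * 10, 1e-8) for i, v in enumerate(ids, 1)]
        shuffled = [variants[i] for i in perm]
        ref = [(h.tag_variant, h.member_variants) for h in prune_to_haplotypes(variants, ld, 0.5)]
        got = [(h.tag_variant, h.member_variants) for h in prune_to_haplotypes(shuffled, ld, 0.5)]
        assert got == ref

    def test_matches_brute_force_on_all_small_patterns(self):
        # exhaustive over all LD matrices on 4 variants with entries {0, 0.9}
        ids = ["a", "b", "c", "d"]
        variants = [(v, i, 1e-8) for i, v in enumerate(ids, 1)]
        pairs = list(itertools.combinations(ids, 2))
        for bits in itertools.product([0.0, 0.9], repeat=len(pairs)):
            pair_r2 = {frozenset(p): v for p, v in zip(pairs, bits)}
            ld = matrix(ids, {p: v for p, v in zip(pairs, bits)})
            got = sorted(
                (h.tag_variant, h.member_variants)
                for h in prune_to_haplotypes(variants, ld, 0.5)
            )
            assert got == brute_force_greedy(variants, pair_r2, 0.5)
            assert sorted(v for _, m in got for v in m) == ids  # partition


class TestAssignTraits:
    def test_published_trait_loads(self, table1):
        records, _, ld = table1
        haps = prune_catalog(records, ld, 0.5)
        by_tag = {h.tag_variant: h for h in haps}
        assert by_tag["rs61348208"].n_traits == 6
        assert by_tag["rs909788"].n_traits == 5
        assert by_tag["rs362307"].n_distinct_traits == 5

    def test_unassignable_record_names_variant_and_gene(self, table1):
        records, _, ld = table1
        haps = prune_catalog(records, ld, 0.5)
        stray = make_record(gene_symbol="HTT", variant_id="rs999")
        with pytest.raises(ValueError, match="rs999.*HTT"):
            assign_traits([stray], haps)

    def test_assignment_preserves_record_count(self, table1):
        records, _, ld = table1
        haps = prune_catalog(records, ld, 0.5)
        assert sum(h.n_traits for h in haps) == len(records)


class TestSeverity:
    def test_singleton(self):
        assert most_severe(["intron_variant"]) == "intron_variant"

    @pytest.mark.parametrize(
        "terms,expected",
        [
            (["intron_variant", "splice_region_variant"], "splice_region_variant"),
            (["3_prime_UTR_variant", "intron_variant"], "3_prime_UTR_variant"),
            (["intronic", "UTR"], "3_prime_UTR_variant"),  # display aliases accepted
            (["missense_variant", "stop_gained"], "stop_gained"),
        ],
    )
    def test_ordering(self, terms, expected):
        assert most_severe(terms) == expected

    def test_unknown_term_is_listed(self):
        with pytest.raises(KeyError, match="made_up_variant"):
            most_severe(["intron_variant", "made_up_variant"])

    def test_duplicate_terms_rejected_in_table(self):
        with pytest.raises(ValueError, match="duplicate"):
            SeverityTable(["a", "a"])

    def test_fixture_annotations_are_in_vocabulary(self, table1):
        _, annotations, _ = table1
        for ann in annotations:
            assert ann.consequence in DEFAULT_SEVERITY
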