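"""Count-trait removal, provenance filtering, dedup, ancestry, OMIM classes."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyqprofile.prioritize import (
    classify_omim_entries,
    dedup_traits,
    filter_peer_reviewed,
    flag_count_traits,
    prioritize_catalog,
    summarize_ancestry,
)
from polyqprofile.types import DEFAULT_COUNT_TRAIT_PATTERNS

from conftest import make_record


class TestCountTraits:
    @pytest.mark.parametrize(
        "label,removed",
        [
            ("neutrophil count", True),
            ("Platelet Count", True),
            ("reticulocyte fraction", True),
            ("educational attainment", False),
            ("county-level income", False),  # 'count' must match as a word
        ],
    )
    def test_default_patterns(self, label, removed):
        kept, out = flag_count_traits([make_record(trait_label=label)],
                                      DEFAULT_COUNT_TRAIT_PATTERNS)
        assert bool(out) is removed
        assert len(kept) + len(out) == 1

    def test_empty_pattern_list_removes_nothing(self):
        records = [make_record(trait_label="platelet count")]
        kept, removed = flag_count_traits(records, [])
        assert kept == records and removed == []

    def test_invalid_regex_is_a_configuration_error(self):
        with pytest.raises(ValueError, match=r"\("):
            flag_count_traits([], ["("])

    def test_partition_exact(self, results):
        catalog, _, _ = results
        kept, removed = flag_count_traits(catalog, DEFAULT_COUNT_TRAIT_PATTERNS)
        assert len(kept) + len(removed) == len(catalog)
        assert set(id(r) for r in kept).isdisjoint(id(r) for r in removed)


class TestPeerReviewed:
    def test_results_fixture_composition(self, results):
        catalog, _, _ = results
        kept, removed, report = filter_peer_reviewed(catalog)
        assert len(removed) == 32
        assert report.removed_by_source == {
            "FinnGen_R6": 4, "UKB_NealeLab_R2": 26, "UKB_SAIGE": 2,
        }
        assert round(100 * len(removed) / len(catalog), 1) == 14.9

    def test_all_peer_reviewed_removes_none(self):
        records = [make_record(pubmed_id="1"), make_record(pubmed_id="2")]
        kept, removed, _ = filter_peer_reviewed(records)
        assert removed == [] and kept == records

    def test_single_non_pubmed_fully_removed(self):
        kept, removed, report = filter_peer_reviewed(
            [make_record(pubmed_id=None, source="UKB_SAIGE")]
        )
        assert kept == [] and len(removed) == 1
        assert report.removed_by_source == {"UKB_SAIGE": 1}


class TestDedup:
    def test_max_l2g_wins(self):
        a = make_record(l2g=0.6, variant_id="rs10")
        b = make_record(l2g=0.8, variant_id="rs20")
        assert dedup_traits([a, b]) == [b]

    def test_same_trait_different_genes_both_kept(self):
        a = make_record(gene_symbol="G1")
        b = make_record(gene_symbol="G2")
        assert len(dedup_traits([a, b])) == 2

    def test_three_way_tie_resolved_by_variant_id(self):
        recs = [make_record(variant_id=v) for v in ("rs3", "rs1", "rs2")]
        [winner] = dedup_traits(recs)
        assert winner.variant_id == "rs1"

    def test_table1_dedup_leaves_37_unique_pairs(self, table1):
        records, _, _ = table1
        assert len(dedup_traits(records)) == 37  # the two same-trait rows collapse

    @given(st.permutations(range(6)))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_invariant_to_input_order(self, perm):
        base = [
            make_record(l2g=0.6, variant_id="rs5"),
            make_record(l2g=0.8, variant_id="rs6"),
            make_record(trait_label="other", l2g=0.7, variant_id="rs7"),
            make_record(gene_symbol="G2", variant_id="rs8"),
            make_record(l2g=0.8, gwas_p=1e-12, variant_id="rs9"),
            make_record(l2g=0.8, gwas_p=1e-12, variant_id="rs4"),
        ]
        shuffled = [base[i] for i in perm]
        assert dedup_traits(shuffled) == dedup_traits(base)


class TestAncestry:
    def test_exclusive_vs_any_counting(self):
        records = [
            make_record(study_id="S1", ancestries=frozenset({"EUR"})),
            make_record(study_id="S2", ancestries=frozenset({"EUR", "EAS"})),
        ]
        s = summarize_ancestry(records)
        assert s.n_exclusive["EUR"] == 1 and s.n_any["EUR"] == 2

    def test_study_cited_by_three_records_counts_once(self):
        records = [make_record(study_id="S1", variant_id=f"rs{i}") for i in range(3)]
        assert summarize_ancestry(records).n_studies == 1

    def test_41_study_fixture_percentages(self, ancestry_records):
        s = summarize_ancestry(ancestry_records)
        assert s.n_studies == 41
        assert s.pct_exclusive["EUR"] == 75.6
        assert s.pct_any == {"EUR": 97.6, "EAS": 22.0, "AFR": 12.2}

    def test_empty_ancestry_studies_counted_separately(self):
        records = [
            make_record(study_id="S1"),
            make_record(study_id="S2", ancestries=frozenset()),
        ]
        s = summarize_ancestry(records)
        assert s.n_studies == 1 and s.n_excluded_no_ancestry == 1


class TestOmim:
    def test_fixture_classification(self, results):
        _, _, omim = results
        counts = classify_omim_entries(omim)
        assert counts == {"mendelian": 8, "susceptibility": 4, "cag_related": 4}

    def test_empty_table(self):
        assert classify_omim_entries([]) == {
            "mendelian": 0, "susceptibility": 0, "cag_related": 0,
        }


class TestFullPrioritization:
    def test_report_partitions_input(self, results):
        catalog, _, _ = results
        deduped, report = prioritize_catalog(catalog, DEFAULT_COUNT_TRAIT_PATTERNS)
        assert report.n_in == 215
        assert report.n_in == (
            report.n_retained + report.n_removed_count_traits + report.n_removed_non_pubmed
        )
        assert report.n_unique_after_dedup == len(deduped)
        # count-based hematological genes drop out entirely
        assert "TBP" not in report.genes_retained
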