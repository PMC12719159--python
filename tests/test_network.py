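"""Shared-trait network construction, isolation, export."""

import itertools
import xml.etree.ElementTree as ET

import networkx as nx
import pytest

from polyqprofile.network import build_network, export_network, isolated_genes
from polyqprofile.simulate import CatalogSpec, generate_catalog

from conftest import make_record


def brute_force_edges(records):
    """Oracle: pairwise intersections of per-gene normalized trait sets."""
    traits = {}
    for r in records:
        traits.setdefault(r.gene_symbol, set()).add(r.trait_key)
    out = {}
    for a, b in itertools.combinations(sorted(traits), 2):
        common = traits[a] & traits[b]
        if common:
            out[(a, b)] = len(common)
    return out


class TestBuild:
    def test_single_shared_trait(self):
        records = [
            make_record(gene_symbol="G1", trait_label="a"),
            make_record(gene_symbol="G1", trait_label="b"),
            make_record(gene_symbol="G2", trait_label="b"),
            make_record(gene_symbol="G2", trait_label="c"),
        ]
        net = build_network(records)
        assert net.edges == {("G1", "G2"): 1}
        assert net.shared_trait_lists[("G1", "G2")] == {"b"}
        assert net.nodes == {"G1": 2, "G2": 2}

    def test_single_gene_has_no_edges(self):
        net = build_network([make_record()])
        assert net.edges == {}

    def test_duplicates_and_order_do_not_matter(self):
        records = [
            make_record(gene_symbol="G1", trait_label="b"),
            make_record(gene_symbol="G2", trait_label="b"),
        ]
        doubled = records * 3
        assert build_network(doubled).edges == build_network(records[::-1]).edges

    def test_planted_shared_counts_recovered(self):
        spec = CatalogSpec(
            n_genes=4,
            traits_per_gene=8,
            shared_trait_pairs=(("G1", "G2", 3), ("G2", "G3", 1)),
            seed=7,
        )
        records = generate_catalog(spec)
        net = build_network(records)
        assert net.edges[("G1", "G2")] == 3
        assert net.edges[("G2", "G3")] == 1
        assert ("G1", "G4") not in net.edges
        assert net.edges == brute_force_edges(records)

    def test_results_fixture_structure(self, results):
        catalog, _, _ = results
        net = build_network(catalog)
        genes = {r.gene_symbol for r in catalog}
        assert isolated_genes(net, genes) == {"TBP", "CACNA1A"}
        # the strongest edge links the two most pleiotropic genes
        assert max(net.edges, key=net.edges.get) == ("ATXN1", "HTT")
        assert net.edges == brute_force_edges(catalog)

    def test_random_catalogs_match_brute_force(self):
        for seed in range(25):
            spec = CatalogSpec(
                n_genes=5, traits_per_gene=10,
                shared_trait_pairs=(("G1", "G3", seed % 4), ("G2", "G5", 2)),
                seed=seed,
            )
            records = generate_catalog(spec)
            assert build_network(records).edges == brute_force_edges(records)


class TestIsolation:
    def test_complete_sharing_leaves_none_isolated(self):
        records = [make_record(gene_symbol=g, trait_label="t") for g in ("G1", "G2", "G3")]
        net = build_network(records)
        assert isolated_genes(net, {"G1", "G2", "G3"}) == set()

    def test_gene_absent_from_records_is_isolated(self):
        net = build_network([make_record(gene_symbol="G1")])
        assert isolated_genes(net, {"G1", "G9"}) == {"G1", "G9"}


class TestExport:
    def test_edge_list_has_one_data_row(self, tmp_path):
        records = [
            make_record(gene_symbol="G1", trait_label="b"),
            make_record(gene_symbol="G2", trait_label="b"),
        ]
        path = export_network(build_network(records), tmp_path / "edges.tsv")
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 2
        assert lines[1].split("\t") == ["G1", "G2", "1", "b"]

    def test_edge_list_round_trip(self, tmp_path, results):
        catalog, _, _ = results
        net = build_network(catalog)
        path = export_network(net, tmp_path / "edges.tsv")
        weights = {}
        for line in path.read_text().strip().splitlines()[1:]:
            a, b, w, _ = line.split("\t")
            weights[(a, b)] = int(w)
        assert weights == dict(net.edges)

    def test_graphml_is_valid_and_faithful(self, tmp_path, results):
        catalog, _, _ = results
        net = build_network(catalog)
        path = export_network(net, tmp_path / "net.graphml", "graphml")
        tree = ET.parse(path)  # well-formed XML
        assert tree.getroot().tag.endswith("graphml")
        back = nx.read_graphml(path)
        assert {tuple(sorted(e)): d["weight"] for *e, d in back.edges(data=True)} == dict(
            net.edges
        )

    def test_unknown_format_rejected(self, results):
        catalog, _, _ = results
        with pytest.raises(ValueError, match="format"):
            export_network(build_network(catalog), "x", "dot")
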