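"""Weighted gene-gene network of shared trait associations.

Nodes are genes, weighted by the number of distinct normalized traits the
gene is associated with; an edge joins two genes iff they share at least one
normalized trait, weighted by the number of distinct shared traits.
Correlated-but-distinct labels count separately (no ontology collapsing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx

from .types import AssociationRecord

__all__ = ["TraitNetwork", "build_network", "isolated_genes", "export_network"]

log = logging.getLogger("polyqprofile.network")


@dataclass(frozen=True)
class TraitNetwork:
    nodes: Mapping[str, int]  # gene -> distinct trait count
    edges: Mapping[tuple[str, str], int]  # sorted pair -> shared trait count
    shared_trait_lists: Mapping[tuple[str, str], frozenset[str]]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for gene, count in sorted(self.nodes.items()):
            g.add_node(gene, trait_count=count)
        for (a, b), weight in sorted(self.edges.items()):
            g.add_edge(
                a, b, weight=weight,
                shared_traits=";".join(sorted(self.shared_trait_lists[(a, b)])),
            )
        return g


def build_network(records: Sequence[AssociationRecord]) -> TraitNetwork:
    """Build the shared-trait network from a (pre-filtered) catalog.

    Duplicate records and input order do not affect the result (set
    semantics on normalized trait labels).
    """
    traits_by_gene: dict[str, set[str]] = {}
    for r in records:
        traits_by_gene.setdefault(r.gene_symbol, set()).add(r.trait_key)
    nodes = {g: len(ts) for g, ts in traits_by_gene.items()}
    edges: dict[tuple[str, str], int] = {}
    shared: dict[tuple[str, str], frozenset[str]] = {}
    for a, b in combinations(sorted(traits_by_gene), 2):
        common = traits_by_gene[a] & traits_by_gene[b]
        if common:
            edges[(a, b)] = len(common)
            shared[(a, b)] = frozenset(common)
    return TraitNetwork(nodes=nodes, edges=edges, shared_trait_lists=shared)


def isolated_genes(network: TraitNetwork, all_genes: set[str]) -> set[str]:
    """Genes in ``all_genes`` incident to no shared-trait edge."""
    connected = {g for pair in network.edges for g in pair}
    return set(all_genes) - connected


def export_network(network: TraitNetwork, path, format: str = "edge_list_tsv") -> Path:
    """Write the network as an edge-list TSV or GraphML file.

    Edge list columns: gene_a, gene_b, weight, shared_traits (semicolon
    joined); genes in lexicographic order within a pair.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "edge_list_tsv":
        lines = ["gene_a\tgene_b\tweight\tshared_traits"]
        for (a, b), weight in sorted(network.edges.items()):
            lines.append(
                f"{a}\t{b}\t{weight}\t" + ";".join(sorted(network.shared_trait_lists[(a, b)]))
            )
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif format == "graphml":
        nx.write_graphml(network.to_networkx(), path)
    else:
        raise ValueError(f"unknown network export format {format!r}")
    return path
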