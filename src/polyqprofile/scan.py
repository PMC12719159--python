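"""Phenome-wide scan: L2G filtering, category summaries, threshold sweep.

The scan stage takes the raw gene-trait association catalog and keeps the
signals whose locus-to-gene score strictly exceeds the cutoff (default 0.5,
the score's recommended operating point). Robustness of the cutoff is
assessed by counting retained records along a grid of thresholds.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .types import AssociationRecord, normalize_trait

__all__ = ["ScanSummary", "filter_by_l2g", "summarize_scan", "threshold_sweep"]

log = logging.getLogger("polyqprofile.scan")


@dataclass(frozen=True)
class ScanSummary:
    """Counts describing one association catalog (or a filtered slice of it)."""

    n_signals: int
    n_unique_traits: int
    n_gene_trait_pairs_retained: int
    genes_retained: frozenset[str]
    per_category_counts: Mapping[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_signals": self.n_signals,
            "n_unique_traits": self.n_unique_traits,
            "n_gene_trait_pairs_retained": self.n_gene_trait_pairs_retained,
            "genes_retained": sorted(self.genes_retained),
            "per_category_counts": dict(sorted(self.per_category_counts.items())),
        }


def filter_by_l2g(
    records: Sequence[AssociationRecord], cutoff: float
) -> list[AssociationRecord]:
    """Keep records with ``l2g`` strictly greater than ``cutoff``.

    Input order is preserved; a record at exactly the cutoff is dropped.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must be in [0,1], got {cutoff!r}")
    return [r for r in records if r.l2g > cutoff]


def summarize_scan(records: Sequence[AssociationRecord]) -> ScanSummary:
    """Summarize a catalog: signal count, unique normalized traits, distinct
    gene-trait pairs, genes present, and per-category counts."""
    traits = {r.trait_key for r in records}
    pairs = {(r.gene_symbol, r.trait_key) for r in records}
    categories = Counter(r.trait_category for r in records)
    return ScanSummary(
        n_signals=len(records),
        n_unique_traits=len(traits),
        n_gene_trait_pairs_retained=len(pairs),
        genes_retained=frozenset(r.gene_symbol for r in records),
        per_category_counts=dict(categories),
    )


def threshold_sweep(
    records: Sequence[AssociationRecord], grid: Sequence[float]
) -> dict[float, int]:
    """Count retained records at each cutoff of an increasing grid.

    Equivalent by construction to ``len(filter_by_l2g(records, c))`` at every
    grid point; counts are weakly decreasing along the grid.
    """
    grid = list(grid)
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("sweep grid must be strictly increasing")
    scores = sorted(r.l2g for r in records)
    out: dict[float, int] = {}
    import bisect

    for cutoff in grid:
        if not 0.0 <= cutoff <= 1.0:
            raise ValueError(f"grid cutoff must be in [0,1], got {cutoff!r}")
        # number of scores strictly greater than cutoff
        out[cutoff] = len(scores) - bisect.bisect_right(scores, cutoff)
    return out
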