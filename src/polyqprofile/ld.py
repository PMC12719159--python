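"""Independent-signal (haplotype) identification by LD pruning.

GWAS index variants at a locus are grouped into haplotypes: a haplotype is a
set of variants in high LD (r2 strictly above the cutoff, default 0.5) with
a single tag variant that proxies the group. Pruning is greedy and
tag-centric: variants are processed in a canonical order, the first
unassigned variant becomes a tag, and every later unassigned variant whose
r2 with that tag exceeds the cutoff joins its haplotype. Tags of distinct
haplotypes therefore satisfy r2 <= cutoff pairwise.

The canonical processing order is ascending genomic position (ties broken by
ascending GWAS p-value, then lexicographic variant id), so the tag is the
5'-most member of its haplotype. Membership can depend on processing order
under a greedy rule, so the order is fixed and documented; it also differs
from single-linkage clustering (a variant in LD with a member but not with
the tag starts a new haplotype).

Missing r2 entries are treated as 0 (conservative toward declaring
independence) with a logged warning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .types import AssociationRecord, LDMatrix

__all__ = ["HaplotypeSignal", "prune_to_haplotypes", "assign_traits", "prune_catalog"]

log = logging.getLogger("polyqprofile.ld")


@dataclass
class HaplotypeSignal:
    """One independent signal: a tag variant plus the variants it proxies."""

    gene_symbol: str
    haplotype_index: int  # 1-based, per gene, by ascending tag position
    tag_variant: str
    member_variants: tuple[str, ...]
    assigned_traits: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def n_traits(self) -> int:
        return len(self.assigned_traits)

    @property
    def n_distinct_traits(self) -> int:
        return len({t for t, _, _ in self.assigned_traits})


def _canonical_order(
    variants: Sequence[tuple[str, int, float]]
) -> list[tuple[str, int, float]]:
    return sorted(variants, key=lambda v: (v[1], v[2], v[0]))


def prune_to_haplotypes(
    variants: Sequence[tuple[str, int, float]],
    ld: LDMatrix,
    r2_cutoff: float = 0.5,
    gene_symbol: str = "",
) -> list[HaplotypeSignal]:
    """Greedy tag-centric LD pruning of index variants into haplotypes.

    Parameters
    ----------
    variants
        ``(variant_id, pos, gwas_p)`` triples; every id must be present in
        ``ld``. Duplicated ids are rejected.
    ld
        Pairwise r2 matrix. Missing pairs count as r2 = 0 (warned).
    r2_cutoff
        Strict threshold: a variant joins a tag iff r2(tag, v) > cutoff.

    Returns haplotypes indexed per gene by ascending tag position. The
    member sets partition the input variants.
    """
    if not 0.0 <= r2_cutoff < 1.0:
        raise ValueError(f"r2_cutoff must be in [0,1), got {r2_cutoff!r}")
    ids = [v[0] for v in variants]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate variant ids in pruning input")
    absent = [v for v in ids if v not in ld]
    if absent:
        raise ValueError(f"variants absent from LD matrix: {absent}")

    ordered = _canonical_order(variants)
    pos_of = {v: p for v, p, _ in ordered}
    assigned: set[str] = set()
    missing_pairs = 0
    haplotypes: list[tuple[str, list[str]]] = []
    for tag, _, _ in ordered:
        if tag in assigned:
            continue
        members = [tag]
        assigned.add(tag)
        for vid, _, _ in ordered:
            if vid in assigned:
                continue
            if ld.is_missing(tag, vid):
                missing_pairs += 1
                continue  # missing treated as r2 = 0
            if ld.get(tag, vid) > r2_cutoff:
                members.append(vid)
                assigned.add(vid)
        haplotypes.append((tag, members))
    if missing_pairs:
        log.warning(
            "%s: %d missing r2 entries treated as 0 during pruning",
            gene_symbol or "locus",
            missing_pairs,
        )
    haplotypes.sort(key=lambda h: (pos_of[h[0]], h[0]))
    return [
        HaplotypeSignal(
            gene_symbol=gene_symbol,
            haplotype_index=i,
            tag_variant=tag,
            member_variants=tuple(members),
        )
        for i, (tag, members) in enumerate(haplotypes, start=1)
    ]


def assign_traits(
    records: Sequence[AssociationRecord], haplotypes: Sequence[HaplotypeSignal]
) -> list[HaplotypeSignal]:
    """Attach each gene-trait record to the haplotype containing its index
    variant (within the record's gene). Records whose variant belongs to no
    haplotype of their gene raise ``ValueError`` naming variant and gene.
    """
    lookup: dict[tuple[str, str], HaplotypeSignal] = {}
    for h in haplotypes:
        h.assigned_traits = []
        for v in h.member_variants:
            lookup[(h.gene_symbol, v)] = h
    for r in records:
        h = lookup.get((r.gene_symbol, r.variant_id))
        if h is None:
            raise ValueError(
                f"variant {r.variant_id} (gene {r.gene_symbol}) is not a member of "
                "any haplotype for that gene"
            )
        h.assigned_traits.append((r.trait_label, r.study_id, r.l2g))
    return list(haplotypes)


def prune_catalog(
    records: Sequence[AssociationRecord],
    ld_by_gene: Mapping[str, LDMatrix],
    r2_cutoff: float = 0.5,
) -> list[HaplotypeSignal]:
    """Prune each gene's index variants and assign its trait records.

    The per-variant GWAS p fed to the canonical order is the minimum across
    that variant's records; the position is taken from the records (which
    must agree).
    """
    by_gene: dict[str, dict[str, tuple[int, float]]] = {}
    for r in records:
        gene = by_gene.setdefault(r.gene_symbol, {})
        if r.variant_id in gene:
            pos, p = gene[r.variant_id]
            if pos != r.pos:
                raise ValueError(
                    f"conflicting positions for {r.variant_id} in {r.gene_symbol}"
                )
            gene[r.variant_id] = (pos, min(p, r.gwas_p))
        else:
            gene[r.variant_id] = (r.pos, r.gwas_p)
    out: list[HaplotypeSignal] = []
    for gene in sorted(by_gene):
        if gene not in ld_by_gene:
            raise ValueError(f"no LD matrix provided for gene {gene}")
        variants = [(v, pos, p) for v, (pos, p) in by_gene[gene].items()]
        haps = prune_to_haplotypes(variants, ld_by_gene[gene], r2_cutoff, gene_symbol=gene)
        out.extend(haps)
    assign_traits(records, out)
    return out
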