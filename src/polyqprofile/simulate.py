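"""Seeded synthetic-data generators.

``generate_catalog`` emulates an Open Targets Genetics style gene-trait
association pull: opaque trait tokens, a controllable fraction of records
above the L2G operating point, a controllable fraction lacking PubMed
provenance, and exactly-planted shared-trait structure between gene pairs
(so network recovery can be checked against construction).

``generate_ld_blocks`` emulates haplotype block structure directly at the
r-squared level: within-block pairs sit strictly above the pruning cutoff,
between-block pairs strictly below, with a small uniform jitter clipped to
keep both sides of the cutoff. No genotypes or phasing are simulated.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .types import AssociationRecord, LDMatrix

__all__ = ["CatalogSpec", "LDBlockSpec", "generate_catalog", "generate_ld_blocks"]

log = logging.getLogger("polyqprofile.simulate")


@dataclass(frozen=True)
class CatalogSpec:
    """Parameters of a synthetic association catalog.

    ``traits_per_gene`` is the exact number of trait records per gene;
    ``l2g_mix`` the fraction of non-planted records drawn above the 0.5
    operating point (planted shared-trait records are always drawn above it
    so the planted network structure survives the standard filter);
    ``provenance_mix`` the expected fraction of records lacking a PubMed id;
    ``shared_trait_pairs`` plants (geneA, geneB, n_shared) exactly.
    """

    n_genes: int
    traits_per_gene: int
    l2g_mix: float = 1.0
    category_mix: Mapping[str, float] = field(
        default_factory=lambda: {"measurement": 0.8, "disease": 0.2}
    )
    provenance_mix: float = 0.0
    shared_trait_pairs: tuple[tuple[str, str, int], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.traits_per_gene < 0:
            raise ValueError("traits_per_gene must be >= 0")
        for name in ("l2g_mix", "provenance_mix"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v!r}")
        total = sum(self.category_mix.values())
        if abs(total - 1.0) > 1e-9 or any(p < 0 for p in self.category_mix.values()):
            raise ValueError("category_mix must be non-negative and sum to 1")

    @property
    def gene_names(self) -> list[str]:
        return [f"G{i + 1}" for i in range(self.n_genes)]


def generate_catalog(spec: CatalogSpec) -> list[AssociationRecord]:
    """Generate a synthetic catalog; deterministic given ``spec.seed``.

    Raises ``ValueError`` if planted shared counts exceed ``traits_per_gene``
    for any gene, or name genes outside the spec.
    """
    genes = spec.gene_names
    gene_set = set(genes)
    shared_per_gene: dict[str, int] = {g: 0 for g in genes}
    for a, b, k in spec.shared_trait_pairs:
        if a not in gene_set or b not in gene_set:
            raise ValueError(f"shared pair names unknown gene: ({a}, {b})")
        if a == b:
            raise ValueError("shared pair must involve two distinct genes")
        if k < 0:
            raise ValueError("shared count must be >= 0")
        shared_per_gene[a] += k
        shared_per_gene[b] += k
    for g, k in shared_per_gene.items():
        if k > spec.traits_per_gene:
            raise ValueError(
                f"infeasible spec: gene {g} needs {k} shared traits but has "
                f"traits_per_gene={spec.traits_per_gene}"
            )

    rng = np.random.default_rng(spec.seed)
    categories = sorted(spec.category_mix)
    probs = np.array([spec.category_mix[c] for c in categories])

    # assign trait labels: planted shared labels first, then unique fillers
    traits_by_gene: dict[str, list[str]] = {g: [] for g in genes}
    for i, (a, b, k) in enumerate(spec.shared_trait_pairs):
        for j in range(k):
            label = f"shared trait {i + 1}.{j + 1} ({a}-{b})"
            traits_by_gene[a].append(label)
            traits_by_gene[b].append(label)
    planted = {g: len(ts) for g, ts in traits_by_gene.items()}
    for g in genes:
        for j in range(spec.traits_per_gene - planted[g]):
            traits_by_gene[g].append(f"trait {g}.{j + 1}")

    records: list[AssociationRecord] = []
    counter = 0
    for gi, g in enumerate(genes):
        for ti, label in enumerate(traits_by_gene[g]):
            counter += 1
            is_planted = ti < planted[g]
            if is_planted or rng.random() < spec.l2g_mix:
                l2g = float(rng.uniform(0.5 + 1e-6, 1.0))
            else:
                l2g = float(rng.uniform(0.0, 0.5))
            no_pubmed = rng.random() < spec.provenance_mix
            category = categories[int(rng.choice(len(categories), p=probs))]
            records.append(
                AssociationRecord(
                    gene_symbol=g,
                    gene_id=f"ENSG{gi + 1:011d}",
                    trait_label=label,
                    trait_category=category,
                    study_id=f"SIM{counter:05d}",
                    pubmed_id=None if no_pubmed else f"9{counter:07d}",
                    source="UKB_NealeLab_R2" if no_pubmed else "GWAS_catalog",
                    l2g=round(l2g, 6),
                    variant_id=f"rs{90000000 + counter}",
                    chrom=str(gi % 22 + 1),
                    pos=1_000_000 + counter * 100,
                    gwas_p=float(10.0 ** -rng.uniform(8, 30)),
                    effect_type="NA",
                    ancestries=frozenset({"EUR"}),
                )
            )
    log.info("generated catalog: %d records, %d genes (seed %d)",
             len(records), spec.n_genes, spec.seed)
    return records


@dataclass(frozen=True)
class LDBlockSpec:
    """Block-structured LD over index variants at the r-squared level."""

    block_sizes: tuple[int, ...]
    within_r2: float
    between_r2: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.block_sizes or any(s < 1 for s in self.block_sizes):
            raise ValueError("block_sizes must be non-empty positive integers")
        if not 0.0 <= self.between_r2 < self.within_r2 <= 1.0:
            raise ValueError("require 0 <= between_r2 < within_r2 <= 1")


def generate_ld_blocks(
    spec: LDBlockSpec,
    variant_ids: Optional[Sequence[str]] = None,
    cutoff: float = 0.5,
) -> LDMatrix:
    """Generate a block LD matrix; deterministic given ``spec.seed``.

    Within-block entries jitter around ``within_r2`` and between-block
    entries around ``between_r2``, with uniform jitter of at most 0.05
    clipped so the two sides stay strictly on opposite sides of ``cutoff``
    (pruning at that cutoff recovers the blocks exactly). Requires
    ``between_r2 < cutoff < within_r2``.
    """
    if not spec.between_r2 < cutoff < spec.within_r2:
        raise ValueError(
            f"cutoff {cutoff} must separate between_r2 {spec.between_r2} "
            f"and within_r2 {spec.within_r2}"
        )
    n = sum(spec.block_sizes)
    if variant_ids is None:
        variant_ids = [f"v{i + 1:03d}" for i in range(n)]
    variant_ids = list(variant_ids)
    if len(variant_ids) != n:
        raise ValueError(f"need {n} variant ids, got {len(variant_ids)}")

    margin = 1e-6
    amp_within = min(0.05, spec.within_r2 - cutoff - margin, 1.0 - spec.within_r2)
    amp_between = min(0.05, cutoff - spec.between_r2 - margin, spec.between_r2)
    amp_within = max(amp_within, 0.0)
    amp_between = max(amp_between, 0.0)

    block_of = np.repeat(np.arange(len(spec.block_sizes)), spec.block_sizes)
    rng = np.random.default_rng(spec.seed)
    r2 = np.empty((n, n))
    for i in range(n):
        r2[i, i] = 1.0
        for j in range(i + 1, n):
            if block_of[i] == block_of[j]:
                val = spec.within_r2 + rng.uniform(-amp_within, amp_within)
            else:
                val = spec.between_r2 + rng.uniform(-amp_between, amp_between)
            r2[i, j] = r2[j, i] = round(float(np.clip(val, 0.0, 1.0)), 6)
    return LDMatrix(variant_ids, r2)
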