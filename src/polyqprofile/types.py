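"""Domain types shared by every pipeline stage.

The pipeline consumes snapshot tables emulating the genomic databases a
phenome-wide drug-target characterization draws on: a GWAS gene-trait
association catalog with locus-to-gene (L2G) scores, per-variant functional
annotations, pairwise LD (r-squared) matrices over index variants, per-gene
druggability-relevant feature profiles (constraint, tissue specificity,
molecular interactions), and OMIM-style phenotype entries.

All types are plain frozen-where-possible dataclasses; table parsing and
row-level validation live in :mod:`polyqprofile.io`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "AssociationRecord",
    "VariantAnnotation",
    "LDMatrix",
    "GeneFeatureProfile",
    "OmimEntry",
    "ThresholdConfig",
    "DEFAULT_COUNT_TRAIT_PATTERNS",
    "BIOBANK_SOURCES",
    "normalize_trait",
]

#: Sources that are biobank-level releases rather than peer-reviewed papers.
#: A record from one of these is expected to lack a PubMed id.
BIOBANK_SOURCES = frozenset({"FinnGen_R6", "UKB_NealeLab_R2", "UKB_SAIGE"})

#: Default patterns flagging count-based traits (e.g. blood cell counts),
#: which attract numerous generic associations genome-wide and are removed
#: during trait prioritization. Overridable via ThresholdConfig.
DEFAULT_COUNT_TRAIT_PATTERNS = (
    r"\bcounts?\b",
    r"\berythrocyte\b",
    r"\bleukocyte\b",
    r"\bplatelet\b",
    r"\bneutrophil\b",
    r"\breticulocyte\b",
    r"\bmonocyte\b",
    r"\blymphocyte\b",
    r"\beosinophil\b",
    r"\bbasophil\b",
)


def normalize_trait(label: str) -> str:
    """Canonical trait-label form: case-folded, whitespace-collapsed.

    Used everywhere two trait labels are compared (uniqueness, dedup,
    shared-trait network edges). No ontology mapping is attempted.
    """
    return re.sub(r"\s+", " ", label.strip()).casefold()


@dataclass(frozen=True)
class AssociationRecord:
    """One gene-trait GWAS association signal.

    ``l2g`` is the Open Targets style locus-to-gene score in [0, 1]; higher
    means stronger support that this gene is causal for the signal.
    ``pubmed_id`` is None for biobank-level releases not indexed in PubMed.
    ``ancestries`` holds GWAS cohort ancestry labels (e.g. {"EUR", "EAS"}).
    """

    gene_symbol: str
    gene_id: str
    trait_label: str
    trait_category: str
    study_id: str
    source: str
    l2g: float
    variant_id: str
    chrom: str
    pos: int
    gwas_p: float
    pubmed_id: Optional[str] = None
    effect: Optional[float] = None
    effect_ci_low: Optional[float] = None
    effect_ci_high: Optional[float] = None
    effect_type: str = "NA"  # beta | odds_ratio | NA
    ancestries: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not 0.0 <= self.l2g <= 1.0:
            raise ValueError(f"l2g must be in [0,1], got {self.l2g!r}")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos!r}")
        if not 0.0 < self.gwas_p <= 1.0:
            raise ValueError(f"gwas_p must be in (0,1], got {self.gwas_p!r}")
        if self.effect_type not in ("beta", "odds_ratio", "NA"):
            raise ValueError(f"unknown effect_type {self.effect_type!r}")
        if self.effect_type == "odds_ratio" and self.effect is not None and self.effect <= 0:
            raise ValueError("odds_ratio effect must be positive")

    @property
    def peer_reviewed(self) -> bool:
        return self.pubmed_id is not None

    @property
    def trait_key(self) -> str:
        return normalize_trait(self.trait_label)


@dataclass(frozen=True)
class VariantAnnotation:
    """Predicted functional annotation of one index variant."""

    variant_id: str
    consequence: str
    cadd: Optional[float] = None
    effect_allele: str = ""
    eur_af: Optional[float] = None
    splice_flag: Optional[bool] = None
    eqtl_gene_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.cadd is not None and self.cadd < 0:
            raise ValueError(f"cadd must be >= 0, got {self.cadd!r}")
        if self.eur_af is not None and not 0.0 <= self.eur_af <= 1.0:
            raise ValueError(f"eur_af must be in [0,1], got {self.eur_af!r}")


class LDMatrix:
    """Symmetric pairwise r-squared matrix over a locus's index variants.

    Missing entries are stored as NaN and flagged via :meth:`is_missing`.
    Diagonal is exactly 1.
    """

    def __init__(self, variant_ids: Sequence[str], r2: np.ndarray):
        ids = list(variant_ids)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate variant ids in LD matrix")
        r2 = np.asarray(r2, dtype=float)
        n = len(ids)
        if r2.shape != (n, n):
            raise ValueError(f"r2 must be {n}x{n}, got {r2.shape}")
        with np.errstate(invalid="ignore"):
            if np.any((r2 < 0) | (r2 > 1)):
                raise ValueError("r2 entries must lie in [0,1] (or be missing)")
        finite = ~np.isnan(r2)
        both = finite & finite.T
        if not np.allclose(r2[both], r2.T[both], atol=1e-9):
            raise ValueError("r2 matrix is not symmetric")
        if not np.all(np.isclose(np.diag(r2), 1.0)):
            raise ValueError("r2 diagonal must be exactly 1")
        # symmetrize missingness: a pair is missing only if missing both ways
        r2 = np.where(np.isnan(r2) & ~np.isnan(r2.T), r2.T, r2)
        np.fill_diagonal(r2, 1.0)
        self.variant_ids: list[str] = ids
        self.r2: np.ndarray = r2
        self._index = {v: i for i, v in enumerate(ids)}

    def __len__(self) -> int:
        return len(self.variant_ids)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def get(self, a: str, b: str) -> float:
        """r2 between two variants; NaN if the pair is unobserved."""
        return float(self.r2[self._index[a], self._index[b]])

    def is_missing(self, a: str, b: str) -> bool:
        return bool(np.isnan(self.r2[self._index[a], self._index[b]]))

    def n_missing(self) -> int:
        iu = np.triu_indices(len(self), k=1)
        return int(np.isnan(self.r2[iu]).sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LDMatrix):
            return NotImplemented
        return self.variant_ids == other.variant_ids and np.array_equal(
            self.r2, other.r2, equal_nan=True
        )


@dataclass(frozen=True)
class GeneFeatureProfile:
    """Per-gene druggability-relevant genomic features.

    ``pli``: gnomAD probability of loss-of-function intolerance in [0,1].
    ``oe_lof``: observed/expected loss-of-function variant ratio (lower =
    more constrained). ``tissue_class``: Human Protein Atlas RNA tissue
    specificity category. ``interactions``: (partner, MI score) pairs from a
    molecular-interaction database; MI in [0,1], higher = higher confidence.
    ``druggable_evidence``: any known or predicted drug interaction.
    """

    TISSUE_CLASSES = (
        "tissue_enriched",
        "group_enriched",
        "tissue_enhanced",
        "low_tissue_specificity",
        "not_detected",
    )

    gene_symbol: str
    pli: Optional[float] = None
    oe_lof: Optional[float] = None
    tissue_class: Optional[str] = None
    interactions: tuple[tuple[str, float], ...] = ()
    druggable_evidence: bool = False

    def __post_init__(self) -> None:
        if self.pli is not None and not 0.0 <= self.pli <= 1.0:
            raise ValueError(f"pli must be in [0,1], got {self.pli!r}")
        if self.oe_lof is not None and self.oe_lof < 0:
            raise ValueError(f"oe_lof must be >= 0, got {self.oe_lof!r}")
        if self.tissue_class is not None and self.tissue_class not in self.TISSUE_CLASSES:
            raise ValueError(f"unknown tissue_class {self.tissue_class!r}")
        for partner, mi in self.interactions:
            if not 0.0 <= mi <= 1.0:
                raise ValueError(f"MI score must be in [0,1], got {mi!r} for {partner!r}")


@dataclass(frozen=True)
class OmimEntry:
    """One OMIM-style phenotype entry for a gene, outside its primary disorder."""

    gene_symbol: str
    phenotype_label: str
    mim_number: str
    inheritance: str
    susceptibility_flag: bool
    cag_related_flag: bool

    def __post_init__(self) -> None:
        starts_susc = self.phenotype_label.strip().casefold().startswith("susceptibility to")
        if starts_susc != self.susceptibility_flag:
            raise ValueError(
                "susceptibility_flag must mirror a 'susceptibility to' phenotype label "
                f"({self.gene_symbol}: {self.phenotype_label!r})"
            )


@dataclass
class ThresholdConfig:
    """All tunable cutoffs of the pipeline, with the study's defaults.

    l2g_cutoff 0.5 (association retained iff l2g > cutoff, strict);
    r2_cutoff 0.5 (variants in the same haplotype iff r2 > cutoff, strict);
    pli_cutoff 0.9 (constraint unfavorable iff pli > cutoff, strict);
    mi_cutoff 0.42 / partner_cutoff 10 (interactions unfavorable iff more
    than 10 partners with MI strictly above 0.42).
    """

    l2g_cutoff: float = 0.5
    r2_cutoff: float = 0.5
    pli_cutoff: float = 0.9
    mi_cutoff: float = 0.42
    partner_cutoff: int = 10
    count_trait_patterns: tuple[str, ...] = DEFAULT_COUNT_TRAIT_PATTERNS
    sweep_grid: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(11))
    rng_seed: int = 0
    biobank_sources: frozenset[str] = BIOBANK_SOURCES

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("l2g_cutoff", 0.0, 1.0),
            ("r2_cutoff", 0.0, 1.0),
            ("pli_cutoff", 0.0, 1.0),
            ("mi_cutoff", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name} must be in [{lo},{hi}], got {v!r}")
        if self.partner_cutoff < 0:
            raise ValueError("partner_cutoff must be >= 0")
        grid = tuple(self.sweep_grid)
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("sweep_grid must be strictly increasing")
        for pat in self.count_trait_patterns:
            try:
                re.compile(pat)
            except re.error as exc:  # pragma: no cover - message path
                raise ValueError(f"invalid count-trait pattern {pat!r}: {exc}") from exc

    def with_(self, **kwargs) -> "ThresholdConfig":
        return replace(self, **kwargs)
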