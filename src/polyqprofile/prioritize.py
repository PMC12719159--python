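"""Trait prioritization: count-trait removal, peer-review provenance filter,
per-gene trait deduplication, ancestry summarization, OMIM classification.

Count-based traits (e.g. blood cell counts) attract generic associations
across the genome and are removed to keep informative signals. Provenance
filtering keeps only gene-trait pairs backed by a PubMed-indexed study;
biobank-level releases (FinnGen/UK Biobank rounds) lack PubMed ids and are
dropped, tallied by source. Duplicate traits per gene are collapsed to the
record with the strongest L2G support.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

from .types import AssociationRecord, OmimEntry, normalize_trait

__all__ = [
    "PrioritizationReport",
    "AncestrySummary",
    "flag_count_traits",
    "filter_peer_reviewed",
    "dedup_traits",
    "summarize_ancestry",
    "classify_omim_entries",
    "prioritize_catalog",
]

log = logging.getLogger("polyqprofile.prioritize")


def _round1(x: float) -> float:
    """Half-up rounding to one decimal (the convention used for reported %)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class PrioritizationReport:
    n_in: int = 0
    n_removed_count_traits: int = 0
    n_removed_non_pubmed: int = 0
    removed_by_source: dict[str, int] = field(default_factory=dict)
    n_retained: int = 0
    n_unique_after_dedup: int = 0
    genes_retained: frozenset[str] = frozenset()

    def validate(self) -> None:
        assert self.n_in == (
            self.n_retained + self.n_removed_count_traits + self.n_removed_non_pubmed
        ), "partition violated: kept + removed != input"
        assert sum(self.removed_by_source.values()) == self.n_removed_non_pubmed

    def to_dict(self) -> dict:
        return {
            "n_in": self.n_in,
            "n_removed_count_traits": self.n_removed_count_traits,
            "n_removed_non_pubmed": self.n_removed_non_pubmed,
            "removed_by_source": dict(sorted(self.removed_by_source.items())),
            "n_retained": self.n_retained,
            "n_unique_after_dedup": self.n_unique_after_dedup,
            "genes_retained": sorted(self.genes_retained),
            "dedup_rule": "max l2g, ties by lower gwas_p, then lexicographic variant_id",
        }


@dataclass(frozen=True)
class AncestrySummary:
    """Per-study ancestry representation (a study counts once however many
    records cite it). 'Exclusive' means the study's ancestry set is a
    singleton for that ancestry."""

    n_studies: int
    n_excluded_no_ancestry: int
    n_exclusive: Mapping[str, int]
    n_any: Mapping[str, int]

    @property
    def pct_exclusive(self) -> dict[str, float]:
        return {a: _round1(100.0 * c / self.n_studies) for a, c in self.n_exclusive.items()}

    @property
    def pct_any(self) -> dict[str, float]:
        return {a: _round1(100.0 * c / self.n_studies) for a, c in self.n_any.items()}

    def to_dict(self) -> dict:
        return {
            "n_studies": self.n_studies,
            "n_excluded_no_ancestry": self.n_excluded_no_ancestry,
            "n_exclusive": dict(sorted(self.n_exclusive.items())),
            "n_any": dict(sorted(self.n_any.items())),
            "pct_exclusive": self.pct_exclusive,
            "pct_any": self.pct_any,
        }


def flag_count_traits(
    records: Sequence[AssociationRecord], patterns: Sequence[str]
) -> tuple[list[AssociationRecord], list[AssociationRecord]]:
    """Partition records into (kept, removed) by count-trait patterns.

    A record is removed iff its normalized trait label matches any pattern.
    Invalid regexes raise ``ValueError`` naming the offending pattern.
    """
    compiled = []
    for pat in patterns:
        try:
            compiled.append(re.compile(pat))
        except re.error as exc:
            raise ValueError(f"invalid count-trait pattern {pat!r}: {exc}") from exc
    kept, removed = [], []
    for r in records:
        label = r.trait_key
        (removed if any(p.search(label) for p in compiled) else kept).append(r)
    return kept, removed


def filter_peer_reviewed(
    records: Sequence[AssociationRecord],
) -> tuple[list[AssociationRecord], list[AssociationRecord], PrioritizationReport]:
    """Partition records into (kept, removed) by PubMed provenance.

    Removed records are those with a missing ``pubmed_id``; their source
    fields are tallied in the report.
    """
    kept = [r for r in records if r.peer_reviewed]
    removed = [r for r in records if not r.peer_reviewed]
    report = PrioritizationReport(
        n_in=len(records),
        n_removed_non_pubmed=len(removed),
        removed_by_source=dict(Counter(r.source for r in removed)),
        n_retained=len(kept),
        genes_retained=frozenset(r.gene_symbol for r in kept),
    )
    return kept, removed, report


def dedup_traits(records: Sequence[AssociationRecord]) -> list[AssociationRecord]:
    """One record per (gene, normalized trait): keep the max-L2G record,
    ties broken by lower gwas_p, then lexicographically smallest variant_id.

    Output is sorted by (gene, trait key) so the result does not depend on
    input order.
    """
    best: dict[tuple[str, str], AssociationRecord] = {}
    for r in records:
        key = (r.gene_symbol, r.trait_key)
        cur = best.get(key)
        if cur is None or (-r.l2g, r.gwas_p, r.variant_id) < (
            -cur.l2g,
            cur.gwas_p,
            cur.variant_id,
        ):
            best[key] = r
    return [best[k] for k in sorted(best)]


def summarize_ancestry(records: Sequence[AssociationRecord]) -> AncestrySummary:
    """Summarize GWAS cohort ancestry per study (keyed on study_id).

    Studies with empty ancestry sets are excluded from the denominator and
    counted separately.
    """
    by_study: dict[str, frozenset[str]] = {}
    for r in records:
        prev = by_study.get(r.study_id)
        if prev is not None and prev != r.ancestries:
            raise ValueError(
                f"study {r.study_id} has conflicting ancestry sets: {sorted(prev)} "
                f"vs {sorted(r.ancestries)}"
            )
        by_study[r.study_id] = r.ancestries
    with_data = {s: a for s, a in by_study.items() if a}
    n_excluded = len(by_study) - len(with_data)
    exclusive: Counter[str] = Counter()
    any_: Counter[str] = Counter()
    for ancestries in with_data.values():
        for a in ancestries:
            any_[a] += 1
        if len(ancestries) == 1:
            exclusive[next(iter(ancestries))] += 1
    return AncestrySummary(
        n_studies=len(with_data),
        n_excluded_no_ancestry=n_excluded,
        n_exclusive=dict(exclusive),
        n_any=dict(any_),
    )


def classify_omim_entries(entries: Sequence[OmimEntry]) -> dict[str, int]:
    """Partition OMIM-style entries into Mendelian vs susceptibility classes,
    tallying CAG-repeat-related entries separately."""
    return {
        "mendelian": sum(1 for e in entries if not e.susceptibility_flag),
        "susceptibility": sum(1 for e in entries if e.susceptibility_flag),
        "cag_related": sum(1 for e in entries if e.cag_related_flag),
    }


def prioritize_catalog(
    records: Sequence[AssociationRecord], patterns: Sequence[str]
) -> tuple[list[AssociationRecord], PrioritizationReport]:
    """Full prioritization: count-trait removal, then provenance filter,
    then per-gene trait dedup. Returns the deduplicated records and a
    report whose counts partition the input exactly."""
    kept_ct, removed_ct = flag_count_traits(records, patterns)
    kept, removed_pm, report = filter_peer_reviewed(kept_ct)
    deduped = dedup_traits(kept)
    report.n_in = len(records)
    report.n_removed_count_traits = len(removed_ct)
    report.n_unique_after_dedup = len(deduped)
    report.validate()
    log.info(
        "prioritization: %d in, %d count-trait removed, %d non-PubMed removed, "
        "%d retained (%d unique gene-trait pairs)",
        report.n_in,
        report.n_removed_count_traits,
        report.n_removed_non_pubmed,
        report.n_retained,
        report.n_unique_after_dedup,
    )
    return deduped, report
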