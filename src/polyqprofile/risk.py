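"""Drug-target genomic risk profiling and gene-set comparison.

Each gene is classified favorable/unfavorable on three features empirically
linked to clinical-trial stoppage for safety reasons:

* genetic constraint — unfavorable iff pLI strictly above 0.9 (extremely
  loss-of-function intolerant);
* tissue expression — unfavorable iff the HPA RNA specificity class is
  "low tissue specificity" (broadly expressed);
* molecular interactions — unfavorable iff strictly more than 10 interaction
  partners with MI score strictly above 0.42 (high confidence).

The aggregate safety score is the count of unfavorable features (0-3);
missing features never contribute and are flagged as unknown. Druggability
evidence ("druggable any") is carried through for information but indicates
only that the gene can be perturbed, not that doing so is safe.

Two gene sets are compared on their score distributions with a two-sided
Wilcoxon rank-sum (Mann-Whitney) test — tie-corrected normal approximation
by default, exact enumeration of group assignments for small samples — with
effect size r = |z| / sqrt(n_a + n_b).
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import pandas as pd

from .types import GeneFeatureProfile, ThresholdConfig

__all__ = [
    "FeatureVerdict",
    "ComparisonResult",
    "classify_constraint",
    "classify_expression",
    "classify_interactions",
    "aggregate_scores",
    "rank_sum_compare",
    "compare_gene_sets",
    "verdict_frame",
]

log = logging.getLogger("polyqprofile.risk")

EFFECT_LABELS = ((0.5, "large"), (0.3, "medium"), (0.1, "small"), (0.0, "negligible"))


@dataclass(frozen=True)
class FeatureVerdict:
    """Per-gene feature classification; True = unfavorable, None = unknown."""

    gene_symbol: str
    constraint_unfavorable: Optional[bool]
    expression_unfavorable: Optional[bool]
    interactions_unfavorable: Optional[bool]
    interaction_partner_count: int
    druggable_any: bool
    safety_score: int

    def __post_init__(self) -> None:
        expected = sum(
            1
            for v in (
                self.constraint_unfavorable,
                self.expression_unfavorable,
                self.interactions_unfavorable,
            )
            if v is True
        )
        if self.safety_score != expected:
            raise ValueError("safety_score must equal the count of unfavorable features")


@dataclass(frozen=True)
class ComparisonResult:
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    u_statistic: float
    z_value: float
    p_two_sided: float
    effect_r: float
    effect_label: str
    method: str

    def to_dict(self) -> dict:
        return {
            "n_a": self.n_a,
            "n_b": self.n_b,
            "mean_a": self.mean_a,
            "mean_b": self.mean_b,
            "u_statistic": self.u_statistic,
            "z_value": self.z_value,
            "p_two_sided": self.p_two_sided,
            "effect_r": self.effect_r,
            "effect_label": self.effect_label,
            "method": self.method,
        }

    def summary(self) -> str:
        return (
            f"rank-sum comparison ({self.method}): n_a={self.n_a}, n_b={self.n_b}, "
            f"mean_a={self.mean_a}, mean_b={self.mean_b}, U={self.u_statistic}, "
            f"z={self.z_value:.3f}, p={self.p_two_sided:.3g}, "
            f"r={self.effect_r:.3f} ({self.effect_label})"
        )


def classify_constraint(profile: GeneFeatureProfile, pli_cutoff: float = 0.9) -> Optional[bool]:
    """Unfavorable iff pLI strictly above the cutoff; None if pLI missing."""
    if not 0.0 <= pli_cutoff <= 1.0:
        raise ValueError(f"pli_cutoff must be in [0,1], got {pli_cutoff!r}")
    if profile.pli is None:
        return None
    return profile.pli > pli_cutoff


def classify_expression(profile: GeneFeatureProfile) -> Optional[bool]:
    """Unfavorable iff the gene is broadly expressed (low tissue specificity);
    None if the tissue class is missing."""
    if profile.tissue_class is None:
        return None
    return profile.tissue_class == "low_tissue_specificity"


def classify_interactions(
    profile: GeneFeatureProfile, mi_cutoff: float = 0.42, partner_cutoff: int = 10
) -> tuple[Optional[bool], int]:
    """Count partners with MI strictly above ``mi_cutoff``; unfavorable iff
    that count strictly exceeds ``partner_cutoff``. Returns (verdict, count).

    A gene with no interaction records is treated as having zero
    high-confidence partners (favorable), not unknown: absence of evidence
    in the interaction snapshot is evidence of few partners.
    """
    if not 0.0 <= mi_cutoff <= 1.0:
        raise ValueError(f"mi_cutoff must be in [0,1], got {mi_cutoff!r}")
    if partner_cutoff < 0:
        raise ValueError("partner_cutoff must be >= 0")
    count = sum(1 for _, mi in profile.interactions if mi > mi_cutoff)
    return count > partner_cutoff, count


def aggregate_scores(
    profiles: Sequence[GeneFeatureProfile], cfg: ThresholdConfig | None = None
) -> list[FeatureVerdict]:
    """Classify every gene and compute its safety score (0-3).

    Output is ranked by descending score, ties by gene symbol. Unknown
    features never contribute; ``druggable_any`` never enters the score.
    """
    cfg = cfg or ThresholdConfig()
    verdicts = []
    for p in profiles:
        constraint = classify_constraint(p, cfg.pli_cutoff)
        expression = classify_expression(p)
        interactions, n_partners = classify_interactions(p, cfg.mi_cutoff, cfg.partner_cutoff)
        score = sum(1 for v in (constraint, expression, interactions) if v is True)
        verdicts.append(
            FeatureVerdict(
                gene_symbol=p.gene_symbol,
                constraint_unfavorable=constraint,
                expression_unfavorable=expression,
                interactions_unfavorable=interactions,
                interaction_partner_count=n_partners,
                druggable_any=p.druggable_evidence,
                safety_score=score,
            )
        )
    verdicts.sort(key=lambda v: (-v.safety_score, v.gene_symbol))
    return verdicts


def verdict_frame(verdicts: Sequence[FeatureVerdict]) -> pd.DataFrame:
    """Verdicts as a DataFrame (one row per gene, ranked)."""
    rows = []
    for rank, v in enumerate(verdicts, start=1):
        rows.append(
            {
                "rank": rank,
                "gene_symbol": v.gene_symbol,
                "constraint_unfavorable": v.constraint_unfavorable,
                "expression_unfavorable": v.expression_unfavorable,
                "interactions_unfavorable": v.interactions_unfavorable,
                "interaction_partner_count": v.interaction_partner_count,
                "druggable_any": v.druggable_any,
                "safety_score": v.safety_score,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rank-sum comparison


def _midranks(pooled: Sequence[float]) -> list[float]:
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1  # 1-based average rank of the tied run
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    return ranks


def _u_statistic(ranks: Sequence[float], idx_a: Sequence[int], n_a: int) -> float:
    r_a = sum(ranks[i] for i in idx_a)
    return r_a - n_a * (n_a + 1) / 2


def _tie_corrected_sd(values: Sequence[float], n_a: int, n_b: int) -> float:
    n = n_a + n_b
    ties = Counter(values).values()
    correction = sum(t**3 - t for t in ties) / (n * (n - 1)) if n > 1 else 0.0
    var = n_a * n_b / 12 * ((n + 1) - correction)
    return math.sqrt(max(var, 0.0))


def _effect_label(r: float) -> str:
    for bound, label in EFFECT_LABELS:
        if r >= bound:
            return label
    return "negligible"


def rank_sum_compare(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    method: str = "normal_tie_corrected",
) -> ComparisonResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) comparison of two groups.

    ``normal_tie_corrected`` uses mid-ranks with tie-corrected variance and
    no continuity correction. ``exact_enumeration`` enumerates all
    assignments of the pooled values into groups of the observed sizes
    (feasible for n_a + n_b <= 12) and computes
    p = min(1, 2 * min(P(U <= u_obs), P(U >= u_obs))).

    In both methods z is the tie-corrected normal deviate of U and
    effect_r = |z| / sqrt(n_a + n_b); when all pooled values are identical
    the comparison is degenerate: z = 0, p = 1, r = 0.
    """
    a, b = list(scores_a), list(scores_b)
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    if method not in ("normal_tie_corrected", "exact_enumeration"):
        raise ValueError(f"unknown method {method!r}")
    n_a, n_b = len(a), len(b)
    n = n_a + n_b
    pooled = a + b
    ranks = _midranks(pooled)
    idx_a = range(n_a)
    u = _u_statistic(ranks, idx_a, n_a)
    mu = n_a * n_b / 2
    sd = _tie_corrected_sd(pooled, n_a, n_b)

    if sd == 0.0:  # all pooled values identical
        z, p = 0.0, 1.0
    else:
        z = (u - mu) / sd
        if method == "normal_tie_corrected":
            p = 2.0 * (1.0 - _normal_cdf(abs(z)))
            p = min(max(p, 0.0), 1.0) or math.nextafter(0.0, 1.0)
        else:
            if n > 12:
                raise ValueError(
                    f"exact enumeration supports n_a + n_b <= 12, got {n}"
                )
            lo = hi = 0
            total = 0
            eps = 1e-9
            for combo in combinations(range(n), n_a):
                u_k = _u_statistic(ranks, combo, n_a)
                total += 1
                if u_k <= u + eps:
                    lo += 1
                if u_k >= u - eps:
                    hi += 1
            p = min(1.0, 2.0 * min(lo, hi) / total)

    r = abs(z) / math.sqrt(n)
    return ComparisonResult(
        n_a=n_a,
        n_b=n_b,
        mean_a=round(sum(a) / n_a, 1),
        mean_b=round(sum(b) / n_b, 1),
        u_statistic=u,
        z_value=z,
        p_two_sided=p,
        effect_r=r,
        effect_label=_effect_label(r),
        method=method,
    )


def _normal_cdf(x: float) -> float:
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


def compare_gene_sets(
    profiles_a: Sequence[GeneFeatureProfile],
    profiles_b: Sequence[GeneFeatureProfile],
    cfg: ThresholdConfig | None = None,
    method: str = "normal_tie_corrected",
) -> tuple[ComparisonResult, list[FeatureVerdict], list[FeatureVerdict]]:
    """Score both gene sets and compare their safety-score distributions.

    Returns the comparison (group means reported to one decimal) plus the
    per-gene verdict tables of both sets.
    """
    cfg = cfg or ThresholdConfig()
    verdicts_a = aggregate_scores(profiles_a, cfg)
    verdicts_b = aggregate_scores(profiles_b, cfg)
    result = rank_sum_compare(
        [v.safety_score for v in verdicts_a],
        [v.safety_score for v in verdicts_b],
        method=method,
    )
    log.info(result.summary())
    return result, verdicts_a, verdicts_b
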