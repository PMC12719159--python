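"""Table readers/writers, configuration, and validation.

All tables are UTF-8 TSV with a header row; missing values are encoded as
``"."``. Every parse failure carries row/column provenance. Writers and
readers round-trip records field-by-field.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import yaml

from .types import (
    AssociationRecord,
    GeneFeatureProfile,
    LDMatrix,
    OmimEntry,
    ThresholdConfig,
    VariantAnnotation,
)

__all__ = [
    "MISSING",
    "SchemaError",
    "ValidationError",
    "read_association_table",
    "write_association_table",
    "read_annotation_table",
    "write_annotation_table",
    "read_ld_matrix",
    "write_ld_matrix",
    "read_profile_table",
    "write_profile_table",
    "read_omim_table",
    "write_omim_table",
    "validate_profile_table",
    "read_config",
    "write_config",
]

MISSING = "."

log = logging.getLogger("polyqprofile.io")

ASSOCIATION_COLUMNS = (
    "gene_symbol",
    "gene_id",
    "trait_label",
    "trait_category",
    "study_id",
    "pubmed_id",
    "source",
    "l2g",
    "variant_id",
    "chrom",
    "pos",
    "gwas_p",
    "effect",
    "effect_ci_low",
    "effect_ci_high",
    "effect_type",
    "ancestries",
)

ANNOTATION_COLUMNS = (
    "variant_id",
    "consequence",
    "cadd",
    "effect_allele",
    "eur_af",
    "splice_flag",
    "eqtl_gene_ids",
)

FEATURE_COLUMNS = ("gene_symbol", "pli", "oe_lof", "tissue_class", "druggable_evidence")
INTERACTION_COLUMNS = ("gene_symbol", "partner", "mi_score")
OMIM_COLUMNS = (
    "gene_symbol",
    "phenotype_label",
    "mim_number",
    "inheritance",
    "susceptibility_flag",
    "cag_related_flag",
)


class SchemaError(ValueError):
    """A table is missing required columns or uses an unknown layout."""


class ValidationError(ValueError):
    """One or more rows failed validation; carries row-numbered diagnostics."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


def _opt(value: str) -> Optional[str]:
    return None if value == MISSING or value == "" else value


def _fmt(value) -> str:
    if value is None:
        return MISSING
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _parse_bool(value: str, *, row: int, column: str) -> bool:
    if value in ("true", "True", "1"):
        return True
    if value in ("false", "False", "0"):
        return False
    raise ValueError(f"row {row}: column {column}: not a boolean: {value!r}")


def _data_lines(fh):
    """Yield non-comment lines (lines starting with '#' carry provenance notes)."""
    for line in fh:
        if not line.startswith("#"):
            yield line


def _rows(path, required: Sequence[str]):
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(_data_lines(fh), delimiter="\t")
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, header required")
        missing = [c for c in required if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
        yield from enumerate(reader, start=2)  # header is line 1


# ---------------------------------------------------------------------------
# association catalog


def read_association_table(path, schema: ThresholdConfig | None = None) -> list[AssociationRecord]:
    """Parse a gene-trait association catalog TSV.

    Every row is parsed or rejected; rejection raises :class:`ValidationError`
    carrying line-numbered diagnostics for all bad rows at once.
    """
    records: list[AssociationRecord] = []
    problems: list[str] = []
    for lineno, row in _rows(path, ASSOCIATION_COLUMNS):
        try:
            ancestries = _opt(row["ancestries"])
            records.append(
                AssociationRecord(
                    gene_symbol=row["gene_symbol"],
                    gene_id=row["gene_id"],
                    trait_label=row["trait_label"],
                    trait_category=row["trait_category"],
                    study_id=row["study_id"],
                    pubmed_id=_opt(row["pubmed_id"]),
                    source=row["source"],
                    l2g=float(row["l2g"]),
                    variant_id=row["variant_id"],
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    gwas_p=float(row["gwas_p"]),
                    effect=None if _opt(row["effect"]) is None else float(row["effect"]),
                    effect_ci_low=None
                    if _opt(row["effect_ci_low"]) is None
                    else float(row["effect_ci_low"]),
                    effect_ci_high=None
                    if _opt(row["effect_ci_high"]) is None
                    else float(row["effect_ci_high"]),
                    effect_type=row["effect_type"] if _opt(row["effect_type"]) else "NA",
                    ancestries=frozenset(ancestries.split(",")) if ancestries else frozenset(),
                )
            )
        except (ValueError, KeyError) as exc:
            problems.append(f"row {lineno}: {exc}")
    if problems:
        raise ValidationError(problems)
    log.info("read %d association records from %s", len(records), path)
    return records


def write_association_table(records: Iterable[AssociationRecord], path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(ASSOCIATION_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.gene_symbol,
                    r.gene_id,
                    r.trait_label,
                    r.trait_category,
                    r.study_id,
                    _fmt(r.pubmed_id),
                    r.source,
                    _fmt(r.l2g),
                    r.variant_id,
                    r.chrom,
                    r.pos,
                    _fmt(r.gwas_p),
                    _fmt(r.effect),
                    _fmt(r.effect_ci_low),
                    _fmt(r.effect_ci_high),
                    r.effect_type,
                    ",".join(sorted(r.ancestries)) if r.ancestries else MISSING,
                ]
            )
    return path


# ---------------------------------------------------------------------------
# variant annotations


def read_annotation_table(path) -> list[VariantAnnotation]:
    out: list[VariantAnnotation] = []
    problems: list[str] = []
    for lineno, row in _rows(path, ANNOTATION_COLUMNS):
        try:
            eqtl = _opt(row["eqtl_gene_ids"])
            splice = _opt(row["splice_flag"])
            out.append(
                VariantAnnotation(
                    variant_id=row["variant_id"],
                    consequence=row["consequence"],
                    cadd=None if _opt(row["cadd"]) is None else float(row["cadd"]),
                    effect_allele=row["effect_allele"],
                    eur_af=None if _opt(row["eur_af"]) is None else float(row["eur_af"]),
                    splice_flag=None
                    if splice is None
                    else _parse_bool(splice, row=lineno, column="splice_flag"),
                    eqtl_gene_ids=frozenset(eqtl.split(",")) if eqtl else frozenset(),
                )
            )
        except ValueError as exc:
            problems.append(f"row {lineno}: {exc}")
    if problems:
        raise ValidationError(problems)
    return out


def write_annotation_table(annotations: Iterable[VariantAnnotation], path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(ANNOTATION_COLUMNS)
        for a in annotations:
            writer.writerow(
                [
                    a.variant_id,
                    a.consequence,
                    _fmt(a.cadd),
                    a.effect_allele,
                    _fmt(a.eur_af),
                    _fmt(a.splice_flag),
                    ",".join(sorted(a.eqtl_gene_ids)) if a.eqtl_gene_ids else MISSING,
                ]
            )
    return path


# ---------------------------------------------------------------------------
# LD matrices


def read_ld_matrix(path) -> LDMatrix:
    """Read an LD matrix from long-format TSV (id_a, id_b, r2) or a square
    matrix TSV whose first column is ``variant_id``.

    Unobserved pairs are NaN. Conflicting duplicate pairs
    (|r2_ab - r2_ba| > 1e-9) raise :class:`ValidationError`.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(_data_lines(fh), delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise SchemaError(f"{path}: empty file")
        if header[:3] == ["id_a", "id_b", "r2"]:
            return _read_ld_long(reader, path)
        if header and header[0] == "variant_id":
            return _read_ld_square(header, reader, path)
    raise SchemaError(
        f"{path}: unrecognized LD layout; expected columns (id_a, id_b, r2) "
        "or a square matrix with leading 'variant_id' column"
    )


def _read_ld_long(reader, path) -> LDMatrix:
    pairs: dict[tuple[str, str], float] = {}
    order: list[str] = []
    seen: set[str] = set()
    problems: list[str] = []
    for lineno, row in enumerate(reader, start=2):
        if not row:
            continue
        a, b, val = row[0], row[1], float(row[2])
        for v in (a, b):
            if v not in seen:
                seen.add(v)
                order.append(v)
        key = (min(a, b), max(a, b))
        if key in pairs and abs(pairs[key] - val) > 1e-9:
            problems.append(
                f"row {lineno}: conflicting r2 for pair {a}/{b}: "
                f"{pairs[key]!r} vs {val!r}"
            )
        else:
            pairs[key] = val
    if problems:
        raise ValidationError(problems)
    n = len(order)
    idx = {v: i for i, v in enumerate(order)}
    r2 = np.full((n, n), np.nan)
    np.fill_diagonal(r2, 1.0)
    for (a, b), val in pairs.items():
        r2[idx[a], idx[b]] = val
        r2[idx[b], idx[a]] = val
    mat = LDMatrix(order, r2)
    if mat.n_missing():
        log.warning("%s: %d unobserved variant pairs marked missing", path, mat.n_missing())
    return mat


def _read_ld_square(header, reader, path) -> LDMatrix:
    ids = header[1:]
    n = len(ids)
    r2 = np.full((n, n), np.nan)
    for i, row in enumerate(reader):
        if i >= n:
            raise SchemaError(f"{path}: more rows than header variants")
        for j, cell in enumerate(row[1:]):
            if cell != MISSING:
                r2[i, j] = float(cell)
    return LDMatrix(ids, r2)


def write_ld_matrix(ld: LDMatrix, path, layout: str = "long") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        if layout == "long":
            writer.writerow(["id_a", "id_b", "r2"])
            for i, a in enumerate(ld.variant_ids):
                for j in range(i + 1, len(ld)):
                    if not np.isnan(ld.r2[i, j]):
                        writer.writerow([a, ld.variant_ids[j], _fmt(float(ld.r2[i, j]))])
        elif layout == "square":
            writer.writerow(["variant_id", *ld.variant_ids])
            for i, a in enumerate(ld.variant_ids):
                writer.writerow(
                    [a]
                    + [
                        MISSING if np.isnan(v) else _fmt(float(v))
                        for v in ld.r2[i]
                    ]
                )
        else:
            raise ValueError(f"unknown LD layout {layout!r}")
    return path


# ---------------------------------------------------------------------------
# gene feature profiles


def read_profile_table(features_path, interactions_path=None) -> list[GeneFeatureProfile]:
    """Read per-gene feature profiles, optionally joined with a long-format
    interaction table (gene_symbol, partner, mi_score)."""
    interactions: dict[str, list[tuple[str, float]]] = {}
    if interactions_path is not None:
        problems: list[str] = []
        for lineno, row in _rows(interactions_path, INTERACTION_COLUMNS):
            try:
                interactions.setdefault(row["gene_symbol"], []).append(
                    (row["partner"], float(row["mi_score"]))
                )
            except ValueError as exc:
                problems.append(f"row {lineno}: {exc}")
        if problems:
            raise ValidationError(problems)

    profiles: list[GeneFeatureProfile] = []
    problems = []
    for lineno, row in _rows(features_path, FEATURE_COLUMNS):
        try:
            profiles.append(
                GeneFeatureProfile(
                    gene_symbol=row["gene_symbol"],
                    pli=None if _opt(row["pli"]) is None else float(row["pli"]),
                    oe_lof=None if _opt(row["oe_lof"]) is None else float(row["oe_lof"]),
                    tissue_class=_opt(row["tissue_class"]),
                    druggable_evidence=_parse_bool(
                        row["druggable_evidence"], row=lineno, column="druggable_evidence"
                    ),
                    interactions=tuple(interactions.get(row["gene_symbol"], ())),
                )
            )
        except ValueError as exc:
            problems.append(f"row {lineno}: {exc}")
    if problems:
        raise ValidationError(problems)
    return profiles


def write_profile_table(
    profiles: Iterable[GeneFeatureProfile], features_path, interactions_path=None
) -> Path:
    features_path = Path(features_path)
    features_path.parent.mkdir(parents=True, exist_ok=True)
    profiles = list(profiles)
    with features_path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(FEATURE_COLUMNS)
        for p in profiles:
            writer.writerow(
                [p.gene_symbol, _fmt(p.pli), _fmt(p.oe_lof), _fmt(p.tissue_class),
                 _fmt(p.druggable_evidence)]
            )
    if interactions_path is not None:
        interactions_path = Path(interactions_path)
        with interactions_path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(INTERACTION_COLUMNS)
            for p in profiles:
                for partner, mi in p.interactions:
                    writer.writerow([p.gene_symbol, partner, _fmt(mi)])
    return features_path


def validate_profile_table(profiles: Sequence[GeneFeatureProfile]) -> dict[str, list[str]]:
    """Report genes with missing features per category.

    Returns a mapping ``category -> [gene, ...]`` with categories
    ``constraint``, ``expression`` and ``interactions``; duplicate gene
    symbols raise :class:`ValidationError` (symbol collisions are rejected
    rather than merged).
    """
    seen: set[str] = set()
    dupes: list[str] = []
    for p in profiles:
        if p.gene_symbol in seen:
            dupes.append(p.gene_symbol)
        seen.add(p.gene_symbol)
    if dupes:
        raise ValidationError([f"duplicate gene_symbol: {g}" for g in sorted(set(dupes))])
    report: dict[str, list[str]] = {"constraint": [], "expression": [], "interactions": []}
    for p in profiles:
        if p.pli is None:
            report["constraint"].append(p.gene_symbol)
        if p.tissue_class is None:
            report["expression"].append(p.gene_symbol)
        if not p.interactions:
            report["interactions"].append(p.gene_symbol)
    return report


# ---------------------------------------------------------------------------
# OMIM entries


def read_omim_table(path) -> list[OmimEntry]:
    out: list[OmimEntry] = []
    problems: list[str] = []
    for lineno, row in _rows(path, OMIM_COLUMNS):
        try:
            out.append(
                OmimEntry(
                    gene_symbol=row["gene_symbol"],
                    phenotype_label=row["phenotype_label"],
                    mim_number=row["mim_number"],
                    inheritance=row["inheritance"],
                    susceptibility_flag=_parse_bool(
                        row["susceptibility_flag"], row=lineno, column="susceptibility_flag"
                    ),
                    cag_related_flag=_parse_bool(
                        row["cag_related_flag"], row=lineno, column="cag_related_flag"
                    ),
                )
            )
        except ValueError as exc:
            problems.append(f"row {lineno}: {exc}")
    if problems:
        raise ValidationError(problems)
    return out


def write_omim_table(entries: Iterable[OmimEntry], path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(OMIM_COLUMNS)
        for e in entries:
            writer.writerow(
                [
                    e.gene_symbol,
                    e.phenotype_label,
                    e.mim_number,
                    e.inheritance,
                    _fmt(e.susceptibility_flag),
                    _fmt(e.cag_related_flag),
                ]
            )
    return path


# ---------------------------------------------------------------------------
# configuration


def read_config(path) -> ThresholdConfig:
    """Load a YAML/JSON-style key-value config into a ThresholdConfig."""
    with Path(path).open(encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: config must be a key-value mapping")
    kwargs = {}
    for key in (
        "l2g_cutoff",
        "r2_cutoff",
        "pli_cutoff",
        "mi_cutoff",
        "partner_cutoff",
        "rng_seed",
    ):
        if key in data:
            kwargs[key] = data[key]
    if "count_trait_patterns" in data:
        kwargs["count_trait_patterns"] = tuple(data["count_trait_patterns"])
    if "sweep_grid" in data:
        kwargs["sweep_grid"] = tuple(data["sweep_grid"])
    if "biobank_sources" in data:
        kwargs["biobank_sources"] = frozenset(data["biobank_sources"])
    unknown = set(data) - {
        "l2g_cutoff", "r2_cutoff", "pli_cutoff", "mi_cutoff", "partner_cutoff",
        "rng_seed", "count_trait_patterns", "sweep_grid", "biobank_sources",
    }
    if unknown:
        raise SchemaError(f"{path}: unknown config key(s): {', '.join(sorted(unknown))}")
    return ThresholdConfig(**kwargs)


def write_config(cfg: ThresholdConfig, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = {
        "l2g_cutoff": cfg.l2g_cutoff,
        "r2_cutoff": cfg.r2_cutoff,
        "pli_cutoff": cfg.pli_cutoff,
        "mi_cutoff": cfg.mi_cutoff,
        "partner_cutoff": cfg.partner_cutoff,
        "count_trait_patterns": list(cfg.count_trait_patterns),
        "sweep_grid": list(cfg.sweep_grid),
        "rng_seed": cfg.rng_seed,
        "biobank_sources": sorted(cfg.biobank_sources),
    }
    with path.open("w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
    return path
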