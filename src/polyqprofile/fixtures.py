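"""Packaged in-study fixtures.

Three fixture families, each built programmatically and also shipped as TSV
under ``polyqprofile/data`` (the shipped files are regenerated bit-identically
by these builders):

* the high-confidence GWAS association table for the five autosomal polyQ
  disorder genes that survived trait prioritization (38 trait rows over 29
  distinct index variants grouped into 21 haplotypes), with per-variant
  annotations and synthetic per-gene block LD matrices consistent with the
  haplotype grouping;
* the Results-level tables: a 215-record L2G>0.5 catalog encoding the stated
  provenance composition (32 biobank-level records lacking PubMed ids:
  FinnGen R6 n=4, UK Biobank Neale lab round 2 n=26, UK Biobank SAIGE n=2),
  gene totals (ATXN1 = 57) and shared-trait network structure (TBP and
  CACNA1A isolated); the 10-gene feature profile table; and the 12-entry
  OMIM phenotype table;
* a 41-study ancestry table (31 exclusively European cohorts).

Everything here other than the association/annotation values transcribed
from the published association table is synthetic: positions are schematic
per-gene coordinates (tag variants placed 5'-most within their haplotype
block), LD matrices are generated block structures, and the 215-record
catalog uses placeholder trait tokens wherever the study names no trait.
"""

from __future__ import annotations

from pathlib import Path

from importlib.resources import files as _resource_files

from . import io as pio
from .simulate import LDBlockSpec, generate_ld_blocks
from .types import AssociationRecord, GeneFeatureProfile, LDMatrix, OmimEntry, VariantAnnotation

__all__ = [
    "GENE_IDS",
    "POLYQ_GENES",
    "build_table1_fixture",
    "build_results_fixtures",
    "build_ancestry_fixture",
    "write_fixture_files",
    "data_path",
    "load_table1_fixture",
    "load_results_fixtures",
    "load_ancestry_fixture",
]

#: The ten polyQ disorder genes (CAG repeat expansion loci).
POLYQ_GENES = (
    "AR", "ATN1", "ATXN1", "ATXN2", "ATXN3", "ATXN7", "CACNA1A", "HTT", "TBP", "THAP11",
)

GENE_IDS = {
    "AR": "ENSG00000169083",
    "ATN1": "ENSG00000111676",
    "ATXN1": "ENSG00000124788",
    "ATXN2": "ENSG00000204842",
    "ATXN3": "ENSG00000066427",
    "ATXN7": "ENSG00000163635",
    "CACNA1A": "ENSG00000141837",
    "HTT": "ENSG00000197386",
    "TBP": "ENSG00000112592",
    "THAP11": "ENSG00000168286",
}

_CHROM = {"ATXN1": "6", "ATXN2": "12", "ATXN7": "3", "CACNA1A": "19", "HTT": "4"}
_BASE_POS = {
    "ATXN1": 16_300_000,
    "ATXN2": 111_400_000,
    "ATXN7": 63_800_000,
    "CACNA1A": 13_200_000,
    "HTT": 3_070_000,
}

# ---------------------------------------------------------------------------
# high-confidence association fixture (38 trait rows, 29 variants, 21 haplotypes)
#
# Haplotype blocks per gene: (tag variant first, then the remaining members).
# The tag is placed 5'-most within its block in the schematic coordinates.

_HAPLOTYPE_BLOCKS: dict[str, list[list[str]]] = {
    "ATXN1": [
        ["rs719316"],
        ["rs17603856"],
        ["rs909788", "rs6459480", "rs9297016", "rs7772172"],
        ["rs6459472"],
        ["rs9367926", "rs6915310"],
        ["rs2237199"],
        ["rs7770062", "rs73366713"],
        ["rs3819405"],
    ],
    "ATXN2": [["rs653178"], ["rs848130"]],
    "ATXN7": [["rs832190"], ["rs3821902"], ["rs13434089"]],
    "CACNA1A": [["rs5021328"], ["rs16003"]],
    "HTT": [
        ["rs363096"],
        ["rs61348208", "rs7685686", "rs82334", "rs2071703"],
        ["rs113928896"],
        ["rs362307"],
        ["rs6828882"],
        ["rs2798297"],
    ],
}

# One tuple per published trait row:
# (gene, trait, category, study_key, variant, p, effect, ci_low, ci_high,
#  effect_type, l2g)
_T1_ROWS = [
    ("ATXN1", "multiple sclerosis", "disease", "bib35",
     "rs719316", 2.00e-13, 1.07, 1.05, 1.09, "odds_ratio", 0.79),
    ("ATXN1", "systemic lupus erythematosus", "disease", "bib36",
     "rs17603856", 3.00e-12, 0.88, 0.85, 0.91, "odds_ratio", 0.79),
    ("ATXN1", "cognitive ability, years of educational attainment or schizophrenia",
     "measurement", "bib37", "rs6459480", 2.00e-10, None, None, None, "NA", 0.69),
    ("ATXN1", "household income", "measurement", "bib38",
     "rs6459480", 5.00e-10, -0.01, -0.02, 0.01, "beta", 0.70),
    ("ATXN1", "educational attainment", "measurement", "bib39",
     "rs9297016", 1.00e-9, -0.01, -0.01, 0.006, "beta", 0.68),
    ("ATXN1", "educational attainment: years of education", "measurement", "bib40",
     "rs7772172", 1.00e-8, -0.01, -0.02, 0.01, "beta", 0.68),
    ("ATXN1", "educational attainment (years of education)", "measurement", "bib39",
     "rs909788", 4.00e-8, -0.01, -0.011, 0.005, "beta", 0.77),
    ("ATXN1", "central corneal thickness", "measurement", "bib41",
     "rs6459472", 3.00e-9, None, None, None, "NA", 0.72),
    ("ATXN1", "male-pattern baldness", "measurement", "bib42",
     "rs6915310", 5.00e-20, 0.04, 0.03, 0.05, "beta", 0.72),
    ("ATXN1", "balding type 1", "measurement", "bib43",
     "rs9367926", 6.00e-12, None, None, None, "NA", 0.71),
    ("ATXN1", "subcutaneous adipose tissue attenuation", "measurement", "bib44",
     "rs2237199", 1.00e-8, 5.67, 3.73, 7.61, "beta", 0.57),
    ("ATXN1", "atrial fibrillation", "disease", "bib45",
     "rs73366713", 1.53e-25, 0.90, 0.88, 0.92, "odds_ratio", 0.55),
    ("ATXN1", "atrial fibrillation", "disease", "bib46",
     "rs7770062", 9.00e-21, 0.90, 0.88, 0.92, "odds_ratio", 0.54),
    ("ATXN1", "breast cancer", "disease", "bib47",
     "rs3819405", 1.65e-8, 0.96, 0.95, 0.97, "odds_ratio", 0.53),
    ("ATXN2", "celiac disease", "disease", "bib48",
     "rs653178", 6.00e-14, 0.83, 0.78, 0.87, "odds_ratio", 0.51),
    ("ATXN2", "type 1 diabetes", "disease", "bib49",
     "rs848130", 1.60e-14, 0.85, 0.82, 0.89, "odds_ratio", 0.67),
    ("ATXN7", "schizophrenia", "disease", "bib50",
     "rs832190", 4.00e-8, None, None, None, "NA", 0.51),
    ("ATXN7", "breast cancer", "disease", "bib47",
     "rs3821902", 2.99e-12, 1.06, 1.05, 1.08, "odds_ratio", 0.54),
    ("ATXN7", "type 2 diabetes", "disease", "bib51",
     "rs13434089", 4.00e-31, -0.06, -0.07, 0.05, "beta", 0.55),
    ("CACNA1A", "appendicular lean mass", "measurement", "bib52",
     "rs5021328", 6.60e-9, -0.01, -0.02, 0.01, "beta", 0.86),
    ("CACNA1A", "positive affect", "measurement", "bib53",
     "rs16003", 3.00e-8, 0.01, 0.00, 0.01, "beta", 0.84),
    ("CACNA1A", "depressive symptoms", "measurement", "bib53",
     "rs16003", 3.00e-8, 0.01, 0.00, 0.01, "beta", 0.84),
    ("HTT", "noncognitive aspects of educational attainment", "measurement", "bib54",
     "rs363096", 1.00e-12, 0.05, 0.04, 0.06, "beta", 0.72),
    ("HTT", "educational attainment: years of education", "measurement", "bib43",
     "rs363096", 1.00e-10, None, None, None, "NA", 0.74),
    ("HTT", "depression", "disease", "bib55",
     "rs7685686", 6.00e-15, 0.983, 0.979, 0.987, "odds_ratio", 0.59),
    ("HTT", "frailty index", "measurement", "bib56",
     "rs82334", 3.10e-10, -0.02, -0.03, 0.02, "beta", 0.54),
    ("HTT", "parental lifespan", "measurement", "bib57",
     "rs61348208", 6.00e-9, 0.23, 0.15, 0.31, "beta", 0.63),
    ("HTT", "gastroesophageal reflux disease", "disease", "bib58",
     "rs7685686", 1.10e-8, 0.97, 0.96, 0.98, "odds_ratio", 0.54),
    ("HTT", "aging traits: health span, parental lifespan or longevity",
     "measurement", "bib59", "rs61348208", 3.00e-8, None, None, None, "NA", 0.62),
    ("HTT", "vertex-wise sulcal depth", "measurement", "bib60",
     "rs2071703", 3.00e-8, 5.57, 3.60, 7.54, "beta", 0.60),
    ("HTT", "highest math class taken", "measurement", "bib39",
     "rs113928896", 2.00e-9, 0.02, 0.01, 0.02, "beta", 0.55),
    ("HTT", "automobile speeding propensity", "measurement", "bib61",
     "rs362307", 6.00e-14, -0.03, -0.04, 0.02, "beta", 0.51),
    ("HTT", "worry/vulnerability: special factor of neuroticism", "measurement", "bib62",
     "rs362307", 1.00e-9, 0.01, 0.005, 0.011, "beta", 0.54),
    ("HTT", "walking pace", "measurement", "bib63",
     "rs362307", 1.00e-9, -0.01, -0.02, 0.01, "beta", 0.54),
    ("HTT", "type 2 diabetes", "disease", "bib64",
     "rs362307", 1.00e-9, 1.08, 1.05, 1.11, "odds_ratio", 0.54),
    ("HTT", "predicted visceral adipose tissue", "measurement", "bib65",
     "rs362307", 2.00e-9, 0.03, 0.02, 0.04, "beta", 0.54),
    ("HTT", "monobrow", "measurement", "bib66",
     "rs6828882", 1.00e-22, None, None, None, "NA", 0.53),
    ("HTT", "metabolic biomarkers", "measurement", "bib67",
     "rs2798297", 1.00e-24, None, None, None, "NA", 0.52),
]

# variant -> (consequence alias, effect allele, EUR allele frequency, CADD)
_T1_VARIANTS = {
    "rs719316": ("intronic", "T", 0.529, 5.92),
    "rs17603856": ("intronic", "G", 0.346, 10.94),
    "rs6459480": ("intronic", "A", 0.509, 1.82),
    "rs9297016": ("intronic", "G", 0.576, 2.57),
    "rs7772172": ("intronic", "G", 0.576, 5.02),
    "rs909788": ("intronic", "C", 0.545, 5.75),
    "rs6459472": ("intronic", "G", 0.573, 2.97),
    "rs6915310": ("intronic", "T", 0.182, 4.27),
    "rs9367926": ("intronic", "G", 0.180, 6.59),
    "rs2237199": ("intronic", "A", 0.112, 3.49),
    "rs73366713": ("intronic", "A", 0.131, 2.84),
    "rs7770062": ("intronic", "A", 0.131, 2.33),
    "rs3819405": ("intronic", "T", 0.340, 12.10),
    "rs653178": ("intronic", "T", 0.534, 1.59),
    "rs848130": ("intronic", "A", 0.192, 2.02),
    "rs832190": ("intronic", "T", 0.603, 0.58),
    "rs3821902": ("intronic", "G", 0.150, 0.81),
    "rs13434089": ("intronic", "C", 0.141, 4.59),
    "rs5021328": ("intronic", "C", 0.644, 0.63),
    "rs16003": ("intronic", "T", 0.463, 8.26),
    "rs363096": ("splice", "C", 0.591, 6.29),
    "rs7685686": ("intronic", "G", 0.433, 6.39),
    "rs82334": ("intronic", "C", 0.323, 4.13),
    "rs61348208": ("intronic", "T", 0.389, 5.46),
    "rs2071703": ("intronic", "C", 0.325, 2.52),
    "rs113928896": ("intronic", "T", 0.143, 0.32),
    "rs362307": ("UTR", "T", 0.063, 3.23),
    "rs6828882": ("intronic", "G", 0.101, 8.54),
    "rs2798297": ("intronic", "A", 0.353, 2.08),
}

_LD_SEEDS = {"ATXN1": 101, "ATXN2": 102, "ATXN7": 103, "CACNA1A": 104, "HTT": 105}


def _variant_positions() -> dict[str, int]:
    """Schematic per-gene positions: haplotype blocks laid out 5'->3' in the
    published order, tag variant 5'-most within its block."""
    pos: dict[str, int] = {}
    for gene, blocks in _HAPLOTYPE_BLOCKS.items():
        for bi, block in enumerate(blocks, start=1):
            for vi, variant in enumerate(block):
                pos[variant] = _BASE_POS[gene] + bi * 10_000 + vi * 100
    return pos


def build_table1_fixture() -> tuple[
    list[AssociationRecord], list[VariantAnnotation], dict[str, LDMatrix]
]:
    """The high-confidence association fixture: 38 trait rows across 5 genes
    and 29 index variants, per-variant annotations, and synthetic per-gene
    block LD (within-block r2 ~ 0.8, between ~ 0.1) matching the published
    haplotype grouping."""
    positions = _variant_positions()
    records = []
    for gene, trait, category, study, variant, p, eff, lo, hi, etype, l2g in _T1_ROWS:
        records.append(
            AssociationRecord(
                gene_symbol=gene,
                gene_id=GENE_IDS[gene],
                trait_label=trait,
                trait_category=category,
                study_id=f"STUDY_{study}",
                pubmed_id=str(30_000_000 + int(study.removeprefix("bib"))),
                source="GWAS_catalog",
                l2g=l2g,
                variant_id=variant,
                chrom=_CHROM[gene],
                pos=positions[variant],
                gwas_p=p,
                effect=eff,
                effect_ci_low=lo,
                effect_ci_high=hi,
                effect_type=etype,
                ancestries=frozenset({"EUR"}),
            )
        )
    annotations = [
        VariantAnnotation(
            variant_id=v,
            consequence=cons,
            cadd=cadd,
            effect_allele=allele,
            eur_af=af,
            splice_flag=(cons == "splice"),
        )
        for v, (cons, allele, af, cadd) in _T1_VARIANTS.items()
    ]
    ld = {
        gene: generate_ld_blocks(
            LDBlockSpec(
                block_sizes=tuple(len(b) for b in blocks),
                within_r2=0.8,
                between_r2=0.1,
                seed=_LD_SEEDS[gene],
            ),
            variant_ids=[v for block in blocks for v in block],
        )
        for gene, blocks in _HAPLOTYPE_BLOCKS.items()
    }
    assert len(records) == 38 and len(annotations) == 29
    return records, annotations, ld


# ---------------------------------------------------------------------------
# Results-level fixtures: 215-record catalog, feature profiles, OMIM entries

# pairwise shared traits (genes sorted), counts chosen so the catalog has
# exactly 149 distinct labels over 215 gene-trait pairs
_SHARED_PAIRS: dict[tuple[str, str], list[str]] = {
    ("ATXN1", "HTT"): [
        "educational attainment", "cognitive ability", "neutrophil count",
        "white blood cell count", "intelligence", "household income",
        "parental lifespan", "depressive symptoms", "smoking initiation",
        "body mass index", "age at first birth", "risk tolerance", "reaction time",
    ],
    ("ATXN1", "ATXN2"): [
        "systolic blood pressure", "triglyceride levels", "standing height",
        "hemoglobin concentration", "mean corpuscular volume", "lymphocyte count",
        "serum urate levels", "hematocrit", "eosinophil count", "monocyte count",
    ],
    ("ATXN1", "ATXN3"): [
        "red blood cell count", "mean platelet volume", "reticulocyte count",
        "platelet distribution width", "mean corpuscular hemoglobin",
        "red cell distribution width", "basophil count", "plateletcrit",
        "immature reticulocyte fraction",
    ],
    ("ATXN2", "ATXN3"): [
        "platelet count", "high light scatter reticulocyte count",
        "mean corpuscular hemoglobin concentration", "granulocyte count",
        "myeloid white cell count", "mean sphered cell volume",
        "mean reticulocyte volume", "reticulocyte percentage",
    ],
    ("ATXN2", "HTT"): [
        "coronary artery disease", "low density lipoprotein cholesterol levels",
        "diastolic blood pressure", "total cholesterol levels", "waist-hip ratio",
        "apolipoprotein B levels", "C-reactive protein levels",
    ],
    ("ATXN3", "HTT"): [
        "neutrophil percentage of white cells", "lymphocyte percentage of white cells",
        "monocyte percentage of white cells", "eosinophil percentage of white cells",
        "sum neutrophil eosinophil count", "erythrocyte count",
    ],
    ("ATXN1", "ATXN7"): [
        "breast cancer", "schizophrenia", "multiple sclerosis",
        "primary biliary cholangitis", "cataract",
    ],
    ("ATXN7", "HTT"): [
        "type 2 diabetes", "depression", "atrial fibrillation", "glaucoma",
    ],
    ("ATXN2", "ATXN7"): ["type 1 diabetes", "celiac disease"],
}

_SHARED_TRIPLE = ("HDL cholesterol levels", ("ATXN1", "ATXN2", "ATXN3"))

_GENE_TOTALS = {
    "ATXN1": 57, "HTT": 40, "ATXN2": 35, "ATXN3": 30,
    "ATXN7": 18, "TBP": 20, "CACNA1A": 15,
}

_DISEASE_LABELS = {
    "breast cancer", "schizophrenia", "multiple sclerosis", "primary biliary cholangitis",
    "cataract", "type 2 diabetes", "depression", "atrial fibrillation", "glaucoma",
    "type 1 diabetes", "celiac disease", "coronary artery disease",
}

# (source, n) slices of the catalog lacking PubMed ids, applied to own-label
# records of specific genes so the composition is deterministic
_NON_PUBMED_PLAN = [
    ("ATXN1", "UKB_NealeLab_R2", 10),
    ("ATXN3", "UKB_NealeLab_R2", 6),
    ("TBP", "UKB_NealeLab_R2", 10),
    ("HTT", "FinnGen_R6", 2),
    ("ATXN2", "FinnGen_R6", 2),
    ("CACNA1A", "UKB_SAIGE", 1),
    ("HTT", "UKB_SAIGE", 1),
]

_RESULTS_CHROM = {
    "ATXN1": "6", "ATXN2": "12", "ATXN3": "14", "ATXN7": "3",
    "CACNA1A": "19", "HTT": "4", "TBP": "6",
}


def _results_trait_plan() -> dict[str, list[str]]:
    """Assign each catalog gene its trait labels: planted shared labels plus
    gene-specific fillers, exactly matching the per-gene totals."""
    traits: dict[str, list[str]] = {g: [] for g in _GENE_TOTALS}
    for (a, b), labels in sorted(_SHARED_PAIRS.items()):
        traits[a].extend(labels)
        traits[b].extend(labels)
    label, genes = _SHARED_TRIPLE
    for g in genes:
        traits[g].append(label)

    fillers = {
        "ATXN1": [f"ATXN1-linked measurement {i:02d}" for i in range(1, 20)],
        "HTT": [f"HTT-linked trait {i:02d}" for i in range(1, 11)],
        "ATXN2": [f"ATXN2-linked trait {i:02d}" for i in range(1, 8)],
        "ATXN3": [
            "granulocyte percentage of myeloid white cells",
            "immature fraction of reticulocytes adjusted",
            "platelet to lymphocyte ratio", "neutrophil to lymphocyte ratio",
            "white blood cell count adjusted", "red blood cell count adjusted",
        ],
        "ATXN7": [
            "age-related macular degeneration", "chronic lymphocytic leukemia",
            "psoriasis", "rheumatoid arthritis", "asthma", "inflammatory bowel disease",
            "prostate cancer",
        ],
        # TBP stays exclusively hematological; labels distinct from every
        # shared hematological label used above
        "TBP": [
            "platelet count adjusted", "basophil percentage of white cells",
            "sum basophil neutrophil count", "platelet side scatter",
            "mean platelet component", "immature platelet fraction",
            "nucleated red blood cell count", "large unstained cell count",
            "reticulocyte hemoglobin content", "erythrocyte sedimentation rate",
            "high fluorescence reticulocyte count", "medium fluorescence reticulocyte count",
            "low fluorescence reticulocyte count", "platelet large cell ratio",
            "monocyte to lymphocyte ratio", "basophil to neutrophil ratio",
            "eosinophil to lymphocyte ratio", "neutrophil side fluorescence",
            "lymphocyte side scatter", "monocyte side scatter",
        ],
        "CACNA1A": [
            "positive affect", "appendicular lean mass", "migraine",
            "brain volume measurement", "cortical surface area", "insomnia",
            "chronotype", "grip strength", "heel bone mineral density",
            "forced vital capacity", "sleep duration", "snoring",
            "alcohol consumption", "coffee consumption", "tea consumption",
        ],
    }
    for g, extra in fillers.items():
        traits[g].extend(extra)
    for g, total in _GENE_TOTALS.items():
        if len(traits[g]) != total:
            raise AssertionError(
                f"fixture construction error: {g} has {len(traits[g])} labels, "
                f"expected {total}"
            )
        if len(set(traits[g])) != total:
            raise AssertionError(f"fixture construction error: duplicate labels for {g}")
    # filler labels must not collide with any shared label (or each other
    # across genes), otherwise the planted network structure would change
    shared_labels = {lab for labs in _SHARED_PAIRS.values() for lab in labs}
    shared_labels.add(_SHARED_TRIPLE[0])
    filler_all = [lab for labs in fillers.values() for lab in labs]
    if set(filler_all) & shared_labels or len(set(filler_all)) != len(filler_all):
        raise AssertionError("fixture construction error: filler label collision")
    return traits


def build_results_fixtures() -> tuple[
    list[AssociationRecord], list[GeneFeatureProfile], list[OmimEntry]
]:
    """The Results-level fixtures: the 215-record L2G>0.5 catalog, the
    10-gene feature profile table, and the 12-entry OMIM phenotype table."""
    traits = _results_trait_plan()

    # deterministic provenance assignment: mark trailing own-label (filler)
    # records of the planned genes, so planted shared labels keep PubMed
    # provenance; (gene, label) -> biobank source for the marked slices
    marked: dict[tuple[str, str], str] = {}
    offsets: dict[str, int] = {g: 0 for g in _GENE_TOTALS}
    for gene, source, n in _NON_PUBMED_PLAN:
        start = len(traits[gene]) - offsets[gene] - n
        for label in traits[gene][start : start + n]:
            marked[(gene, label)] = source
        offsets[gene] += n

    records: list[AssociationRecord] = []
    i = 0
    for gene in sorted(_GENE_TOTALS):
        for label in traits[gene]:
            i += 1
            source = marked.get((gene, label), "GWAS_catalog")
            category = "disease" if label in _DISEASE_LABELS or gene == "ATXN7" else "measurement"
            records.append(
                AssociationRecord(
                    gene_symbol=gene,
                    gene_id=GENE_IDS[gene],
                    trait_label=label,
                    trait_category=category,
                    study_id=f"SYN_S{i:03d}",
                    pubmed_id=None if source != "GWAS_catalog" else f"2{i:07d}",
                    source=source,
                    l2g=round(0.51 + (i * 7) % 49 / 100, 2),
                    variant_id=f"rs9{100000 + i}",
                    chrom=_RESULTS_CHROM[gene],
                    pos=1_000_000 + i * 50,
                    gwas_p=10.0 ** -(8 + i % 22),
                    effect_type="NA",
                    ancestries=frozenset({"EUR"}),
                )
            )
    assert len(records) == 215
    assert len({r.trait_key for r in records}) == 149
    assert sum(1 for r in records if not r.peer_reviewed) == 32

    profiles = _feature_profiles()
    omim = _omim_entries()
    return records, profiles, omim


def _interactions(gene: str, n_high: int, n_low: int = 3) -> tuple[tuple[str, float], ...]:
    """Deterministic interaction list: n_high partners with MI above the 0.42
    confidence threshold and n_low below it."""
    high = tuple(
        (f"{gene}_P{i:03d}", round(0.43 + (i % 50) / 100, 2)) for i in range(1, n_high + 1)
    )
    low = tuple(
        (f"{gene}_L{i:03d}", round(0.20 + (i % 10) / 100, 2)) for i in range(1, n_low + 1)
    )
    return high + low


# (gene, pli, oe_lof, tissue_class, n_high_conf_partners, druggable)
# Constraint is unfavorable (pLI > 0.9) for five genes; the published text
# names four (ATN1, ATXN1, ATXN7, HTT) and shows the fifth only graphically —
# this fixture assigns it to CACNA1A. The group mean safety score is
# invariant to which non-triple-unfavorable gene carries it.
_FEATURE_ROWS = [
    ("AR",      0.55, 0.43, "tissue_enhanced",        22, True),
    ("ATN1",    0.97, 0.12, "low_tissue_specificity", 105, False),
    ("ATXN1",   1.00, 0.08, "low_tissue_specificity", 112, False),
    ("ATXN2",   0.62, 0.46, "low_tissue_specificity", 45, True),
    ("ATXN3",   0.08, 0.74, "low_tissue_specificity", 101, False),
    ("ATXN7",   0.99, 0.15, "low_tissue_specificity", 30, True),
    ("CACNA1A", 1.00, 0.06, "tissue_enriched",        15, True),
    ("HTT",     1.00, 0.03, "low_tissue_specificity", 120, True),
    ("TBP",     0.45, 0.39, "low_tissue_specificity", 28, False),
    ("THAP11",  0.30, 0.58, "low_tissue_specificity", 8, False),
]


def _feature_profiles() -> list[GeneFeatureProfile]:
    return [
        GeneFeatureProfile(
            gene_symbol=gene,
            pli=pli,
            oe_lof=oe,
            tissue_class=tissue,
            interactions=_interactions(gene, n_high),
            druggable_evidence=druggable,
        )
        for gene, pli, oe, tissue, n_high, druggable in _FEATURE_ROWS
    ]


_OMIM_ROWS = [
    ("AR", "androgen insensitivity, partial, with or without breast cancer",
     "312300", "X-linked recessive", False, False),
    ("AR", "androgen insensitivity", "300068", "X-linked recessive", False, False),
    ("AR", "hypospadias 1, X-linked", "300633", "X-linked recessive", False, False),
    ("AR", "susceptibility to: prostate cancer", "176807",
     "autosomal dominant, somatic mutation", True, False),
    ("ATN1", "congenital hypotonia, epilepsy, developmental delay, and digital anomalies",
     "618494", "autosomal dominant", False, False),
    ("ATXN2", "susceptibility to: amyotrophic lateral sclerosis", "183090",
     "autosomal dominant", True, True),
    ("ATXN2", "susceptibility to: Parkinson disease, late-onset", "168600",
     "autosomal dominant, multifactorial", True, True),
    ("CACNA1A", "developmental and epileptic encephalopathy 42", "617106",
     "autosomal dominant", False, False),
    ("CACNA1A", "episodic ataxia, type 2", "108500", "autosomal dominant", False, True),
    ("CACNA1A", "migraine, familial hemiplegic, 1, with progressive cerebellar ataxia",
     "141500", "autosomal dominant", False, False),
    ("HTT", "Lopes-Maciel-Rodan syndrome", "617435", "autosomal recessive", False, False),
    ("TBP", "susceptibility to: Parkinson disease", "168600",
     "autosomal dominant, multifactorial", True, True),
]


def _omim_entries() -> list[OmimEntry]:
    return [
        OmimEntry(
            gene_symbol=g,
            phenotype_label=label,
            mim_number=mim,
            inheritance=inh,
            susceptibility_flag=susc,
            cag_related_flag=cag,
        )
        for g, label, mim, inh, susc, cag in _OMIM_ROWS
    ]


# ---------------------------------------------------------------------------
# ancestry fixture: 41 studies with ancestry data

_ANCESTRY_PLAN = (
    [("EUR",)] * 31
    + [("EUR", "EAS")] * 4
    + [("EUR", "AFR")] * 1
    + [("EUR", "EAS", "AFR")] * 4
    + [("EAS",)] * 1
)


def build_ancestry_fixture() -> list[AssociationRecord]:
    """41 prioritized studies with GWAS Catalog ancestry data: 31 exclusively
    European, European represented in 40, Asian in 9, African in 5."""
    records = []
    for i, ancestries in enumerate(_ANCESTRY_PLAN, start=1):
        records.append(
            AssociationRecord(
                gene_symbol="ATXN1",
                gene_id=GENE_IDS["ATXN1"],
                trait_label=f"ancestry panel trait {i:02d}",
                trait_category="measurement",
                study_id=f"ANC_S{i:02d}",
                pubmed_id=f"3{i:07d}",
                source="GWAS_catalog",
                l2g=0.6,
                variant_id=f"rs8{200000 + i}",
                chrom="6",
                pos=16_000_000 + i * 100,
                gwas_p=1e-9,
                effect_type="NA",
                ancestries=frozenset(ancestries),
            )
        )
    assert len(records) == 41
    return records


# ---------------------------------------------------------------------------
# shipped data files

_FIXTURE_NOTE = (
    "# synthetic fixture: structure transcribed from the published study tables; "
    "positions, LD, identifiers and filler trait labels are synthetic\n"
)


def data_path(name: str) -> Path:
    return Path(_resource_files("polyqprofile").joinpath("data", name))


def write_fixture_files(outdir) -> list[Path]:
    """Write every fixture table as TSV under ``outdir``; returns the paths.

    The shipped package data is produced by this function, so tests can check
    bit-identical regeneration.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []

    t1_records, t1_annotations, t1_ld = build_table1_fixture()
    paths.append(pio.write_association_table(t1_records, outdir / "table1_associations.tsv"))
    paths.append(pio.write_annotation_table(t1_annotations, outdir / "table1_annotations.tsv"))
    for gene, ld in sorted(t1_ld.items()):
        paths.append(pio.write_ld_matrix(ld, outdir / f"table1_ld_{gene}.tsv"))

    catalog, profiles, omim = build_results_fixtures()
    paths.append(pio.write_association_table(catalog, outdir / "results_catalog.tsv"))
    features_path = outdir / "gene_features.tsv"
    pio.write_profile_table(profiles, features_path, outdir / "gene_interactions.tsv")
    features_path.write_text(
        _FIXTURE_NOTE
        + "# the fifth constraint-unfavorable gene is shown only graphically in the "
        "source; this fixture assigns it to CACNA1A (group mean is invariant)\n"
        + features_path.read_text(encoding="utf-8"),
        encoding="utf-8",
    )
    paths.extend([features_path, outdir / "gene_interactions.tsv"])
    paths.append(pio.write_omim_table(omim, outdir / "omim_entries.tsv"))
    paths.append(
        pio.write_association_table(build_ancestry_fixture(), outdir / "ancestry_studies.tsv")
    )
    return paths


def load_table1_fixture() -> tuple[
    list[AssociationRecord], list[VariantAnnotation], dict[str, LDMatrix]
]:
    """Load the shipped high-confidence association fixture."""
    records = pio.read_association_table(data_path("table1_associations.tsv"))
    annotations = pio.read_annotation_table(data_path("table1_annotations.tsv"))
    ld = {
        gene: pio.read_ld_matrix(data_path(f"table1_ld_{gene}.tsv"))
        for gene in _HAPLOTYPE_BLOCKS
    }
    return records, annotations, ld


def load_results_fixtures() -> tuple[
    list[AssociationRecord], list[GeneFeatureProfile], list[OmimEntry]
]:
    """Load the shipped Results-level fixtures."""
    catalog = pio.read_association_table(data_path("results_catalog.tsv"))
    profiles = pio.read_profile_table(
        data_path("gene_features.tsv"), data_path("gene_interactions.tsv")
    )
    omim = pio.read_omim_table(data_path("omim_entries.tsv"))
    return catalog, profiles, omim


def load_ancestry_fixture() -> list[AssociationRecord]:
    return pio.read_association_table(data_path("ancestry_studies.tsv"))
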