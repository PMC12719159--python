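# Methods

This note documents the procedures implemented in `polyqprofile`, the
defaults they use, the design choices made where the published description
left the procedure open, and the limits of what the packaged fixtures and
synthetic generators can show.

## Inputs and conventions

All stages consume snapshot tables (UTF-8 TSV, header required, `.` for
missing values) emulating the databases a phenome-wide drug-target
characterization draws on: an Open Targets Genetics–style gene–trait
association catalog, per-variant functional annotations, pairwise LD (r²)
matrices over index variants, per-gene feature profiles (gnomAD-style
constraint, Human Protein Atlas tissue-specificity class, IntAct-style
interaction records, druggability evidence), and OMIM-style phenotype
entries. Coordinates are 1-based GRCh38-style positions. Genes are keyed on
symbol; duplicate symbols in a profile table are rejected rather than
merged. Lines beginning with `#` are treated as provenance comments.

Trait labels are compared after normalization (case-fold, whitespace
collapse) everywhere — uniqueness counts, per-gene deduplication, and
shared-trait network edges. No ontology mapping is attempted: correlated
but distinct labels (two phrasings of educational attainment, say) count
separately. Whether published "unique trait" counts used raw or
ontology-harmonized labels is not stated; normalized-string uniqueness is
this package's documented choice.

## Phenome-wide scan

A record is retained iff its locus-to-gene score strictly exceeds the
cutoff (`l2g_cutoff`, default 0.5, the score's recommended operating
point); a record exactly at the cutoff is dropped, following the strict
"greater than" convention used for every threshold in this package.
Robustness is assessed by `threshold_sweep` over a grid (default 0.0–1.0 in
0.1 steps); counts are weakly decreasing in the cutoff and equal the filter
applied at each grid point (tested as an oracle equivalence).

## Trait prioritization

*Count-based traits* attract generic associations genome-wide; the
published description names the class by example ("blood cell types")
without an operational rule. The package uses a configurable regex list,
default `\bcounts?\b` plus a short blood-cell lexicon (erythrocyte,
leukocyte, platelet, neutrophil, reticulocyte, monocyte, lymphocyte,
eosinophil, basophil), documented and overridable via config or
`polyq prioritize --patterns`.

*Provenance*: a record is peer-reviewed iff its PubMed id is present;
biobank-level releases (FinnGen R6, UK Biobank Neale lab round 2, UK
Biobank SAIGE) lack PubMed ids by construction. Removed records are tallied
by source.

*Deduplication* keeps, per (gene, normalized trait), the record with the
highest L2G score, breaking ties by lower GWAS p-value and then
lexicographically smallest variant id; output is sorted so the result is
independent of input order. The published text says only that duplicate
traits were filtered; max-L2G is this package's documented representative
choice and is recorded in the report metadata.

*Ancestry* is summarized per study (a study counts once regardless of how
many records cite it); "exclusive" means a singleton ancestry set. Studies
without ancestry data are excluded from the denominator and counted
separately. Percentages are recomputed from integer counts with half-up
rounding to one decimal.

*OMIM entries* partition into Mendelian vs susceptibility classes via the
"susceptibility to" designation of the phenotype label; CAG-repeat-related
entries are tallied separately (they cut across both classes: in the
packaged table, three susceptibility entries and one Mendelian entry carry
the flag).

Note on arithmetic: the published counts linking retained traits, unique
gene-trait associations and distinct signals cannot all be reconciled with
the published association table (38 rows over 29 variants). The pipeline
reports its own counts; on the packaged table, per-gene deduplication
yields 37 unique gene-trait pairs (the two same-gene atrial fibrillation
rows collapse).

## Independent signals (haplotypes)

Index variants at a locus are grouped by greedy, tag-centric LD pruning:
process variants in a canonical order; the first unassigned variant becomes
a tag; every later unassigned variant whose r² with that tag strictly
exceeds `r2_cutoff` (default 0.5) joins that tag's haplotype; repeat. Tags
of distinct haplotypes therefore satisfy r² ≤ cutoff pairwise, every member
is in LD with its tag, and the haplotypes partition the input (all three
are asserted over an exhaustive family of small LD matrices against an
independent brute-force implementation).

Because greedy membership depends on processing order, the order is fixed:
**ascending position, ties by ascending GWAS p-value, then lexicographic
id** — i.e. the tag is the 5'-most member of its haplotype, and haplotype
indices per gene follow tag position. The published analysis delegated
pruning to an external tool whose internal ordering is unspecified; a
position-first order was chosen here because it is deterministic and
reproduces the published tag labels on the packaged fixture, whereas a
significance-first order provably cannot (several published tags are not
the most significant member of their haplotype). Tag-centric joining is
deliberately not transitive closure: in a chain where a–b and b–c are in LD
but a–c is not, the 5'-most variant a absorbs b and c starts a new
haplotype, which differs from single-linkage clustering (surfaced in
tests).

Missing r² entries are treated as 0 — conservative toward declaring
independence — with a logged warning. The choice of LD reference panel
(e.g. excluding founder populations with extended haplotype blocks) is a
data-provenance matter of the input matrix, not an algorithm branch.

Variant consequences are ranked by a shipped severity table following the
conventional Ensembl VEP ordering (most severe first); `most_severe`
returns the minimal-rank term and accepts the short display aliases used in
association tables (`intronic`, `splice`, `UTR`).

## Shared-trait network

Nodes are genes weighted by their number of distinct normalized traits;
an edge joins two genes iff they share at least one normalized trait,
weighted by the count of distinct shared traits. Edges are not weighted by
L2G (relationships are counted, not scored), and duplicate records cannot
inflate weights (set semantics). Exports: edge-list TSV (lexicographic gene
pairs, semicolon-joined shared traits) and GraphML via networkx.

## Drug-target risk profile

Three features are classified per gene, each with a strict threshold and an
`unknown` verdict when the underlying datum is missing:

| feature | unfavorable iff | default |
|---|---|---|
| genetic constraint | pLI > `pli_cutoff` | 0.9 (extremely LoF-intolerant) |
| tissue expression | HPA class = low tissue specificity | — |
| molecular interactions | > `partner_cutoff` partners with MI > `mi_cutoff` | 10 partners, MI 0.42 |

The safety score is the count of `unfavorable = true` verdicts (0–3);
unknown never contributes, a rule this package adds because the published
gene set had complete data. A gene with no interaction records counts zero
high-confidence partners (favorable) rather than unknown: absence from an
interaction snapshot is evidence of few partners. Druggability
("druggable any") is carried through for information only — it indicates
that a gene can be perturbed, not that perturbing it is safe — and never
enters the score. Boundary cases (pLI exactly 0.9, exactly 10 partners, MI
exactly 0.42) are favorable.

Gene sets are compared on score distributions with a two-sided Wilcoxon
rank-sum (Mann–Whitney) test. The default method uses mid-ranks with
tie-corrected variance and no continuity correction; an exact method
enumerates all assignments of the pooled values into groups of the observed
sizes (feasible for n ≤ 12) with the two-sided p defined as
`min(1, 2·min(P(U ≤ u), P(U ≥ u)))`. In both methods the effect size is
`r = |Z|/√N` from the tie-corrected normal deviate, labelled
negligible/small/medium/large at the conventional 0.1/0.3/0.5 boundaries.
When all pooled values are identical the comparison is degenerate:
Z = 0, p = 1, r = 0. The published analysis did not state whether its test
was exact or approximate, one- or two-sided; two-sided tie-corrected normal
is the default here, with the exact method available. Note the two methods
are *not* interchangeable at very small group sizes: with heavy ties and
n per group ≤ ~3 the doubled exact p and the normal tail can differ by more
than 0.5 (e.g. two singleton groups: exact p = 1, normal p ≈ 0.32); their
mean disagreement shrinks as group sizes grow (tested exhaustively over
integer scores at sizes 2 vs 5). Group means are reported to one decimal.

## Fixtures and synthetic data

The packaged fixtures encode the study's structure so the pipeline runs
offline; everything beyond values transcribed from the published
association table is synthetic and labelled as such in the data-file
headers:

* **Association fixture** — 38 trait rows over 29 index variants at five
  genes, transcribed with their L2G, p-values, effects, allele frequencies
  and CADD scores. Positions are schematic (per-gene base coordinate,
  haplotype blocks laid out 5'→3' in published order, tag variant 5'-most);
  the real genomic positions are immaterial to every computation except the
  tag/index ordering they were chosen to reproduce.
* **LD matrices** — generated block structure (within-block r² ≈ 0.8,
  between ≈ 0.1, seeded jitter ≤ 0.05 clipped to keep both sides strictly
  across the 0.5 cutoff), consistent with the published haplotype grouping
  but not estimated from any genotype panel.
* **215-record catalog** — encodes the stated gene totals (ATXN1 = 57),
  149 distinct normalized labels, the provenance composition (32 records
  lacking PubMed ids: 4 + 26 + 2 by source), and the shared-trait structure
  (TBP and CACNA1A isolated; ATXN1–HTT the heaviest edge; ATXN7
  disease-only; ATXN3/TBP exclusively hematological). Filler trait labels
  are placeholders; catalog-level published counts (3,095 signals, 1,467
  traits, the sweep values) derive from a live database snapshot and are
  not reproduced.
* **Feature table** — tissue classes and interaction-partner regimes as
  published (only THAP11 at ≤ 10 high-confidence partners; >100 for HTT,
  ATXN1, ATN1, ATXN3; AR and CACNA1A tissue-restricted). Five genes are
  constraint-unfavorable; the published text names four (ATN1, ATXN1,
  ATXN7, HTT) and shows the fifth only graphically, so the fixture assigns
  it to CACNA1A — the group mean (2.2) is invariant to this choice. pLI,
  o/e and MI values are plausible synthetic numbers on the correct side of
  each threshold, not database values. Per-gene feature values for the HD
  modifier comparison set are not published (only their mean, 1.0), so the
  published p = 7.03 × 10⁻³ and r = 0.628 are not recomputable from
  packaged data; `compare_gene_sets` accepts any user-supplied feature
  table for that comparison.
* **OMIM table** — the 12 published entries with susceptibility and
  CAG-relatedness flags.
* **Ancestry panel** — 41 studies composed to the published margins
  (31 exclusively European; European in 40, Asian in 9, African in 5).

The synthetic generators are pure functions of (spec, seed):
`generate_catalog` plants shared-trait counts exactly (planted records are
drawn above the L2G operating point so the structure survives the standard
filter; the `l2g_mix` fraction applies to the remaining records) and
samples PubMed-missingness binomially; `generate_ld_blocks` emits block
r² structure directly — no genotypes, phasing or allele frequencies are
simulated. Consequently, passing tests demonstrate correctness of the
*procedures* on data with the study's structure; they do not validate
database-dependent quantities, LD estimation, or robustness to ontology
noise in trait labels.

## Numerical and degenerate-input choices

* All thresholds strict; boundary values fall on the favorable/dropped side.
* Half-up decimal rounding for reported percentages and means (matching the
  publication style); percentages recomputed from integer counts.
* LD symmetry tolerance 1e-9 for conflicting duplicate pairs; missing
  entries NaN, symmetrized when observed one way.
* Empty catalogs, empty grids, all-tied score vectors and genes missing
  features all have defined outputs (zero summaries, empty mappings,
  degenerate test results, unknown verdicts) rather than errors; empty
  comparison groups are errors.
* Pipeline outputs are byte-reproducible; the run manifest is the only
  artifact carrying a timestamp.

## Problem sizes used in the checks

The oracle/property checks run at sizes chosen to be exhaustive where
enumeration is cheap: all LD matrices over ≤ 6 variants with r² entries in
{0, 0.9} (~34k cases) against an independent greedy implementation; all
integer-score rank-sum inputs with group sizes ≤ 6 over {0..3} (~44k cases)
against an independent pairwise-comparison enumeration oracle; 1,000 random
catalogs for the threshold-sweep/filter equivalence; 500 random catalogs
with planted sharing for the network/brute-force equivalence.
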