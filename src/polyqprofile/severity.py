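"""Variant-consequence severity ranking.

A total order over Sequence Ontology consequence terms, most severe first,
following the conventional Ensembl VEP ranking. ``most_severe`` picks the
highest-ranked term among a variant's annotations. Short display aliases
used in association tables ("intronic", "splice", "UTR") map onto their SO
terms before ranking.
"""

from __future__ import annotations

from typing import Iterable, Sequence

__all__ = ["SEVERITY_ORDER", "CONSEQUENCE_ALIASES", "SeverityTable", "most_severe"]

#: Consequence terms ordered most severe -> least severe.
SEVERITY_ORDER: tuple[str, ...] = (
    "transcript_ablation",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "stop_gained",
    "frameshift_variant",
    "stop_lost",
    "start_lost",
    "transcript_amplification",
    "inframe_insertion",
    "inframe_deletion",
    "missense_variant",
    "protein_altering_variant",
    "splice_donor_5th_base_variant",
    "splice_region_variant",
    "splice_donor_region_variant",
    "splice_polypyrimidine_tract_variant",
    "incomplete_terminal_codon_variant",
    "start_retained_variant",
    "stop_retained_variant",
    "synonymous_variant",
    "coding_sequence_variant",
    "mature_miRNA_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "non_coding_transcript_exon_variant",
    "intron_variant",
    "NMD_transcript_variant",
    "non_coding_transcript_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "TFBS_ablation",
    "TFBS_amplification",
    "TF_binding_site_variant",
    "regulatory_region_ablation",
    "regulatory_region_amplification",
    "regulatory_region_variant",
    "intergenic_variant",
    "sequence_variant",
)

#: Display aliases accepted wherever a consequence term is expected.
CONSEQUENCE_ALIASES: dict[str, str] = {
    "intronic": "intron_variant",
    "splice": "splice_region_variant",
    "UTR": "3_prime_UTR_variant",
    "utr": "3_prime_UTR_variant",
    "missense": "missense_variant",
    "synonymous": "synonymous_variant",
    "intergenic": "intergenic_variant",
}


class SeverityTable:
    """Ordered consequence vocabulary, most severe first."""

    def __init__(self, terms: Sequence[str] = SEVERITY_ORDER):
        terms = list(terms)
        if len(set(terms)) != len(terms):
            raise ValueError("severity table contains duplicate terms")
        self.terms = tuple(terms)
        self._rank = {t: i for i, t in enumerate(terms)}

    def canonical(self, term: str) -> str:
        term = CONSEQUENCE_ALIASES.get(term, term)
        if term not in self._rank:
            raise KeyError(f"unknown consequence term {term!r}")
        return term

    def rank(self, term: str) -> int:
        return self._rank[self.canonical(term)]

    def __contains__(self, term: str) -> bool:
        return CONSEQUENCE_ALIASES.get(term, term) in self._rank


DEFAULT_SEVERITY = SeverityTable()


def most_severe(terms: Iterable[str], table: SeverityTable = DEFAULT_SEVERITY) -> str:
    """Return the most severe consequence term among ``terms``.

    Unknown terms raise ``KeyError`` listing the offending term. The
    returned term is in canonical SO form even if an alias was supplied.
    """
    terms = list(terms)
    if not terms:
        raise ValueError("most_severe requires at least one consequence term")
    unknown = [t for t in terms if t not in table]
    if unknown:
        raise KeyError(f"unknown consequence terms: {sorted(set(unknown))}")
    return min((table.canonical(t) for t in terms), key=table.rank)
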