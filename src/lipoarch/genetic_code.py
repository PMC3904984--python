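"""Synonymous codon families of the standard (bacterial/archaeal, table 11) code.

Codon-usage statistics only carry information where a choice between
synonymous codons exists, so Met (ATG) and Trp (TGG) — single-codon
families — and the stop codons are tracked separately and excluded from
every "informative" tally.
"""

from __future__ import annotations

from Bio.Data import CodonTable

DEFAULT_TABLE_ID = 11


def build_families(table_id: int = DEFAULT_TABLE_ID) -> dict[str, tuple[str, ...]]:
    """Map amino acid -> sorted tuple of its codons for an NCBI code table."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    fams: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        fams.setdefault(aa, []).append(codon)
    return {aa: tuple(sorted(c)) for aa, c in sorted(fams.items())}


FAMILIES: dict[str, tuple[str, ...]] = build_families()
STOP_CODONS: frozenset[str] = frozenset(
    CodonTable.unambiguous_dna_by_id[DEFAULT_TABLE_ID].stop_codons
)

#: families with a synonymous choice (excludes Met, Trp)
INFORMATIVE_FAMILIES: dict[str, tuple[str, ...]] = {
    aa: codons for aa, codons in FAMILIES.items() if len(codons) > 1
}

CODON_TO_AA: dict[str, str] = {
    codon: aa for aa, codons in FAMILIES.items() for codon in codons
}

INFORMATIVE_CODONS: tuple[str, ...] = tuple(
    codon for aa in sorted(INFORMATIVE_FAMILIES) for codon in INFORMATIVE_FAMILIES[aa]
)

VALID_BASES = frozenset("ACGT")
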