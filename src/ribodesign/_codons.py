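"""Genetic-code helpers shared across modules.

Everything is derived from Biopython's standard (NCBI table 1) codon table,
restricted to the 61 sense codons in DNA alphabet.
"""

from __future__ import annotations

from Bio.Data.CodonTable import unambiguous_dna_by_id

_STANDARD = unambiguous_dna_by_id[1]

#: codon (DNA, upper) -> one-letter amino acid, 61 sense codons
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)

STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)

SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

#: amino acid -> sorted tuple of synonymous codons
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _c, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, ())
    AA_TO_CODONS[_aa] = AA_TO_CODONS[_aa] + (_c,)


def synonyms(codon: str) -> tuple[str, ...]:
    """All codons encoding the same amino acid as ``codon`` (itself included)."""
    return AA_TO_CODONS[CODON_TO_AA[codon]]


def is_synonymous(a: str, b: str) -> bool:
    return CODON_TO_AA.get(a) is not None and CODON_TO_AA.get(a) == CODON_TO_AA.get(b)


def split_codons(dna: str) -> list[str]:
    if len(dna) % 3:
        raise ValueError(f"sequence length {len(dna)} not divisible by 3")
    return [dna[i : i + 3] for i in range(0, len(dna), 3)]
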