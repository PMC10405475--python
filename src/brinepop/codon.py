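"""Genetic-code helpers shared by the generator and the pN/pS machinery.

Translation table 11 (bacteria/archaea/phage). Amino-acid assignments are
identical to the standard code; only start-codon sets differ, which this
package never uses.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[11]

CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))  # 61 codons

BASES = "ACGT"

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def substitution_effect(ref_codon: str, pos: int, alt_base: str) -> str:
    """Effect of a single-base substitution within one codon.

    Returns ``"synonymous"`` or ``"nonsynonymous"``; a change into a stop
    codon is nonsynonymous. ``pos`` is 0..2 within the codon. Raises on a
    reference stop codon or a codon containing N.
    """
    if ref_codon not in CODON_TO_AA:
        raise ValueError(f"reference codon {ref_codon!r} is not a sense codon")
    alt_codon = ref_codon[:pos] + alt_base + ref_codon[pos + 1 :]
    if alt_codon in STOP_CODONS:
        return "nonsynonymous"
    return (
        "synonymous"
        if CODON_TO_AA[alt_codon] == CODON_TO_AA[ref_codon]
        else "nonsynonymous"
    )


def creates_stop(ref_codon: str, pos: int, alt_base: str) -> bool:
    alt_codon = ref_codon[:pos] + alt_base + ref_codon[pos + 1 :]
    return alt_codon in STOP_CODONS
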