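"""Codon-table lookups shared across the simulator, annotator and dN/dS code.

Everything is derived once from the NCBI standard table (Biopython) so the
simulator and the analysis code can never disagree about what a stop is.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

BASES = "ACGT"

#: codon -> amino acid, with '*' for the three stops
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    CODON_TO_AA[_stop] = "*"

STOP_CODONS: tuple[str, ...] = tuple(sorted(_STANDARD.stop_codons))
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c, aa in CODON_TO_AA.items() if aa != "*")
)

#: amino acid -> list of codons (sense only)
AA_TO_CODONS: dict[str, list[str]] = {}
for _codon in SENSE_CODONS:
    AA_TO_CODONS.setdefault(CODON_TO_AA[_codon], []).append(_codon)

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def is_transition(a: str, b: str) -> bool:
    """True if the single-base change a->b is a transition."""
    return (a in _PURINES and b in _PURINES) or (
        a in _PYRIMIDINES and b in _PYRIMIDINES
    )


def translate_codon(codon: str) -> str:
    """Amino acid for a codon; 'X' for codons containing ambiguity."""
    return CODON_TO_AA.get(codon, "X")


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str) -> str:
    """Translate an in-frame nucleotide string; stops as '*', trailing
    partial codon dropped."""
    n = len(seq) - len(seq) % 3
    return "".join(translate_codon(seq[i : i + 3]) for i in range(0, n, 3))
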