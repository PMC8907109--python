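"""Sequence models and residue composition tables for DNA oligos and peptides.

DNA strands are modeled as chains of 2'-deoxynucleosides joined by
phosphodiester linkages (+HPO3 -H2O per bond), written 5'->3' with 1-based
positions.  Synthetic oligonucleotides default to free 5'-OH and 3'-OH
termini; terminal phosphates are configurable per end.  Peptides are chains
of the 20 canonical residues with N-terminal H and C-terminal OH.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Tuple

from .chem import Formula

__all__ = [
    "OligoSequence",
    "PeptideSequence",
    "SequenceError",
    "DEOXYNUCLEOSIDES",
    "NUCLEOBASES",
    "AMINO_ACID_RESIDUES",
    "LINKAGE",
    "HPO3",
    "H2O",
    "oligo_formula",
    "peptide_formula",
    "sequences_from_fasta",
]


class SequenceError(ValueError):
    """Raised for invalid residue letters (reports the 1-based position)."""


H2O = Formula(H=2, O=1)
HPO3 = Formula(H=1, P=1, O=3)
#: phosphodiester bond delta per internucleotide linkage
LINKAGE = HPO3 - H2O

#: 2'-deoxynucleoside (base + deoxyribose - H2O) neutral formulas
DEOXYNUCLEOSIDES = {
    "A": Formula.parse("C10H13N5O3"),
    "C": Formula.parse("C9H13N3O4"),
    "G": Formula.parse("C10H13N5O4"),
    "T": Formula.parse("C10H14N2O5"),
}

#: neutral nucleobase (BH) formulas lost in base-loss fragments
NUCLEOBASES = {
    "A": Formula.parse("C5H5N5"),
    "C": Formula.parse("C4H5N3O"),
    "G": Formula.parse("C5H5N5O"),
    "T": Formula.parse("C5H6N2O2"),
}

#: 2-deoxyribose, for the internal-consistency identity dN = base + sugar - H2O
_DEOXYRIBOSE = Formula.parse("C5H10O4")

#: amino-acid residue (monomer - H2O) formulas, one-letter code
AMINO_ACID_RESIDUES = {
    "G": Formula.parse("C2H3NO"),
    "A": Formula.parse("C3H5NO"),
    "S": Formula.parse("C3H5NO2"),
    "P": Formula.parse("C5H7NO"),
    "V": Formula.parse("C5H9NO"),
    "T": Formula.parse("C4H7NO2"),
    "C": Formula.parse("C3H5NOS"),
    "L": Formula.parse("C6H11NO"),
    "I": Formula.parse("C6H11NO"),
    "N": Formula.parse("C4H6N2O2"),
    "D": Formula.parse("C4H5NO3"),
    "Q": Formula.parse("C5H8N2O2"),
    "K": Formula.parse("C6H12N2O"),
    "E": Formula.parse("C5H7NO3"),
    "M": Formula.parse("C5H9NOS"),
    "H": Formula.parse("C6H7N3O"),
    "F": Formula.parse("C9H9NO"),
    "R": Formula.parse("C6H12N4O"),
    "Y": Formula.parse("C9H9NO2"),
    "W": Formula.parse("C11H10N2O"),
}


def _validate(residues: str, alphabet: Iterable[str], what: str) -> None:
    allowed = set(alphabet)
    if len(residues) < 1:
        raise SequenceError(f"empty {what} sequence")
    for pos, letter in enumerate(residues, start=1):
        if letter not in allowed:
            raise SequenceError(
                f"invalid {what} residue {letter!r} at position {pos}"
            )


@dataclass(frozen=True)
class OligoSequence:
    """A DNA strand written 5'->3'; position 1 is the 5' terminus."""

    residues: str
    name: str = "oligo"
    five_prime_end: str = "OH"
    three_prime_end: str = "OH"

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        _validate(self.residues, DEOXYNUCLEOSIDES, "DNA")
        for end in (self.five_prime_end, self.three_prime_end):
            if end not in ("OH", "phosphate"):
                raise SequenceError(f"terminus must be 'OH' or 'phosphate', got {end!r}")

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self):
            raise IndexError(f"position {position} outside 1..{len(self)}")
        return self.residues[position - 1]

    @property
    def formula(self) -> Formula:
        return oligo_formula(self)


@dataclass(frozen=True)
class PeptideSequence:
    """A peptide in one-letter code; position 1 is the N-terminus."""

    residues: str
    name: str = "peptide"

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        _validate(self.residues, AMINO_ACID_RESIDUES, "peptide")

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, position: int) -> str:
        if not 1 <= position <= len(self):
            raise IndexError(f"position {position} outside 1..{len(self)}")
        return self.residues[position - 1]

    @property
    def formula(self) -> Formula:
        return peptide_formula(self)


def oligo_formula(seq: OligoSequence) -> Formula:
    """Neutral-molecule formula: nucleosides + (n-1) linkages + terminal phosphates."""
    total = Formula()
    for letter in seq.residues:
        total = total + DEOXYNUCLEOSIDES[letter]
    total = total + LINKAGE * (len(seq) - 1)
    if seq.five_prime_end == "phosphate":
        total = total + HPO3
    if seq.three_prime_end == "phosphate":
        total = total + HPO3
    return total.require_nonnegative()


def peptide_formula(seq: PeptideSequence) -> Formula:
    """Neutral-molecule formula: residue sum + H2O."""
    total = H2O
    for letter in seq.residues:
        total = total + AMINO_ACID_RESIDUES[letter]
    return total.require_nonnegative()


def sequences_from_fasta(path: str | Path) -> List[Tuple[str, str]]:
    """Read (record-id, sequence) pairs from a FASTA file."""
    from Bio import SeqIO

    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records
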