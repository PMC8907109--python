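"""Theoretical CID fragment enumeration for oligonucleotides and peptides.

Oligonucleotide backbone cleavage follows the McLuckey a/b/c/d (5'-retaining)
and w/x/y/z (3'-retaining) nomenclature.  With fragments built as
``sum(nucleosides) + (k-1) x linkage`` the end-group deltas are:

===========  ============  ===========  ============
5' series    3'-end delta  3' series    5'-end delta
===========  ============  ===========  ============
a            -H2O          w            +HPO3
b            +0            x            +HPO3 - H2O
c            +HPO3 - H2O   y            +0
d            +HPO3         z            -H2O
===========  ============  ===========  ============

so every complementary pair conserves mass: a_i + w_{n-i} = M, and likewise
b/x, c/y, d/z.  Internal fragments arise from two cleavages and carry the
5'-end chemistry of a 3' series together with the 3'-end chemistry of a 5'
series; the label ``w7:a8`` means the overlap of fragment w7 with fragment
a8.  "-B" marks the additional loss of a neutral nucleobase, by default the
base at the fragment's 3'-side cleavage residue.

Peptide CID fragments are the usual b (residue sum), a (b - CO) and
y (residue sum + H2O) ions, plus amide- and a-type internal fragments.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Tuple, Union

from .chem import Formula
from .polymers import (
    AMINO_ACID_RESIDUES,
    DEOXYNUCLEOSIDES,
    H2O,
    HPO3,
    LINKAGE,
    NUCLEOBASES,
    OligoSequence,
    PeptideSequence,
)

__all__ = [
    "FragmentIon",
    "OLIGO_5PRIME_SERIES",
    "OLIGO_3PRIME_SERIES",
    "THREE_PRIME_END_DELTA",
    "FIVE_PRIME_END_DELTA",
    "CO",
    "NH3",
    "precursor",
    "enumerate_oligo_terminal",
    "enumerate_oligo_internal",
    "enumerate_peptide",
    "fragments_to_tsv",
]

OLIGO_5PRIME_SERIES = ("a", "b", "c", "d")
OLIGO_3PRIME_SERIES = ("w", "x", "y", "z")

#: delta applied at the 3' cut end of a 5'-retaining (a/b/c/d) fragment
THREE_PRIME_END_DELTA = {
    "a": Formula() - H2O,
    "b": Formula(),
    "c": HPO3 - H2O,
    "d": HPO3,
}
#: delta applied at the 5' cut end of a 3'-retaining (w/x/y/z) fragment
FIVE_PRIME_END_DELTA = {
    "w": HPO3,
    "x": HPO3 - H2O,
    "y": Formula(),
    "z": Formula() - H2O,
}

CO = Formula(C=1, O=1)
NH3 = Formula(N=1, H=3)

Polymer = Union[OligoSequence, PeptideSequence]


@dataclass(frozen=True)
class FragmentIon:
    """A neutral cleavage product of an oligo or peptide.

    ``start``/``end`` are the 1-based inclusive sequence positions the
    fragment covers; ``base_losses`` records (position, base letter) pairs
    for nucleobase losses; ``neutral_losses`` are small-molecule deltas
    (H2O, NH3, ...) already subtracted from ``formula``.
    """

    parent: Polymer
    kind: str  # terminal5 | terminal3 | internal | precursor
    label: str
    start: int
    end: int
    formula: Formula
    series: Tuple[str, ...] = ()
    base_losses: Tuple[Tuple[int, str], ...] = ()
    neutral_losses: Tuple[Formula, ...] = ()

    def __post_init__(self) -> None:
        n = len(self.parent)
        if not (1 <= self.start <= self.end <= n):
            raise ValueError(f"covered interval {self.start}..{self.end} outside 1..{n}")
        for pos, _base in self.base_losses:
            if not self.start <= pos <= self.end:
                raise ValueError(f"base loss at {pos} outside covered interval")

    @property
    def neutral_mass(self) -> float:
        return self.formula.monoisotopic_mass

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _oligo_segment(seq: OligoSequence, start: int, end: int) -> Formula:
    total = Formula()
    for pos in range(start, end + 1):
        total = total + DEOXYNUCLEOSIDES[seq[pos]]
    return total + LINKAGE * (end - start)


def precursor(seq: Polymer) -> FragmentIon:
    """The intact (neutral) strand or peptide as a fragment-like record."""
    return FragmentIon(
        parent=seq,
        kind="precursor",
        label=seq.name,
        start=1,
        end=len(seq),
        formula=seq.formula,
    )


def _with_neutral_losses(
    frag: FragmentIon, neutral_losses: Sequence[Formula]
) -> List[FragmentIon]:
    out = [frag]
    for loss in neutral_losses:
        out.append(
            FragmentIon(
                parent=frag.parent,
                kind=frag.kind,
                label=f"{frag.label}-{loss.hill()}",
                start=frag.start,
                end=frag.end,
                formula=frag.formula - loss,
                series=frag.series,
                base_losses=frag.base_losses,
                neutral_losses=frag.neutral_losses + (loss,),
            )
        )
    return out


def enumerate_oligo_terminal(
    seq: OligoSequence,
    series: Iterable[str] = ("a", "w"),
    base_loss: str = "none",
    neutral_losses: Sequence[Formula] = (),
) -> List[FragmentIon]:
    """All single-cleavage fragments of the selected series.

    For an n-mer each series yields indices 1..n-1.  ``base_loss`` may be
    ``"none"``, ``"at-cleavage"`` (lose the base of the residue adjacent to
    the cleaved bond, the dominant channel in DNA CID) or ``"any"`` (lose any
    one base within the fragment).
    """
    series = [s.lower() for s in series]
    unknown = set(series) - set(OLIGO_5PRIME_SERIES) - set(OLIGO_3PRIME_SERIES)
    if unknown:
        raise ValueError(f"unknown oligo series: {sorted(unknown)}")
    if base_loss not in ("none", "at-cleavage", "any"):
        raise ValueError(f"invalid base_loss mode {base_loss!r}")
    n = len(seq)
    out: List[FragmentIon] = []
    for ser in series:
        five_prime = ser in OLIGO_5PRIME_SERIES
        for i in range(1, n):
            if five_prime:
                start, end = 1, i
                formula = _oligo_segment(seq, start, end) + THREE_PRIME_END_DELTA[ser]
                if seq.five_prime_end == "phosphate":
                    formula = formula + HPO3
                cleavage_pos = i
                kind = "terminal5"
            else:
                start, end = n - i + 1, n
                formula = _oligo_segment(seq, start, end) + FIVE_PRIME_END_DELTA[ser]
                if seq.three_prime_end == "phosphate":
                    formula = formula + HPO3
                cleavage_pos = n - i + 1
                kind = "terminal3"
            base_positions: List[int] = []
            if base_loss == "at-cleavage":
                base_positions = [cleavage_pos]
            elif base_loss == "any":
                base_positions = list(range(start, end + 1))
            frag = FragmentIon(
                parent=seq, kind=kind, label=f"{ser}{i}", start=start, end=end,
                formula=formula, series=(ser,),
            )
            out.extend(_with_neutral_losses(frag, neutral_losses))
            for pos in base_positions:
                base = seq[pos]
                lost = FragmentIon(
                    parent=seq,
                    kind=kind,
                    label=f"{ser}{i}-B({base})",
                    start=start,
                    end=end,
                    formula=formula - NUCLEOBASES[base],
                    series=(ser,),
                    base_losses=((pos, base),),
                )
                out.extend(_with_neutral_losses(lost, neutral_losses))
    return out


def enumerate_oligo_internal(
    seq: OligoSequence,
    series3: Iterable[str] = ("w",),
    series5: Iterable[str] = ("a",),
    base_loss: str = "none",
) -> List[FragmentIon]:
    """Double-cleavage internal fragments from a 3' series x 5' series pair.

    A 3'-series fragment of index i covers positions n-i+1..n and a 5'-series
    fragment of index j covers 1..j; their proper overlap p..q = (n-i+1)..j
    with 1 < p <= q < n is the internal fragment, labeled ``"w{i}:a{j}"``.
    Its 5' end carries the 3'-series chemistry and its 3' end the 5'-series
    chemistry.  ``base_loss="at-3'-cleavage"`` additionally loses the neutral
    base at position q (labeled ``"-B"``).
    """
    series3 = [s.lower() for s in series3]
    series5 = [s.lower() for s in series5]
    if set(series3) - set(OLIGO_3PRIME_SERIES):
        raise ValueError(f"series3 must be among {OLIGO_3PRIME_SERIES}")
    if set(series5) - set(OLIGO_5PRIME_SERIES):
        raise ValueError(f"series5 must be among {OLIGO_5PRIME_SERIES}")
    if base_loss not in ("none", "at-3'-cleavage"):
        raise ValueError(f"invalid base_loss mode {base_loss!r}")
    n = len(seq)
    out: List[FragmentIon] = []
    for s3, s5 in itertools.product(series3, series5):
        for i in range(1, n):  # 3'-series index
            p = n - i + 1
            if p <= 1:
                continue
            for j in range(1, n):  # 5'-series index
                q = j
                if q < p or q >= n:
                    continue
                formula = (
                    _oligo_segment(seq, p, q)
                    + FIVE_PRIME_END_DELTA[s3]
                    + THREE_PRIME_END_DELTA[s5]
                )
                frag = FragmentIon(
                    parent=seq,
                    kind="internal",
                    label=f"{s3}{i}:{s5}{j}",
                    start=p,
                    end=q,
                    formula=formula,
                    series=(s3, s5),
                )
                out.append(frag)
                if base_loss == "at-3'-cleavage":
                    base = seq[q]
                    out.append(
                        FragmentIon(
                            parent=seq,
                            kind="internal",
                            label=f"{s3}{i}:{s5}{j}-B",
                            start=p,
                            end=q,
                            formula=formula - NUCLEOBASES[base],
                            series=(s3, s5),
                            base_losses=((q, base),),
                        )
                    )
    return out


def enumerate_peptide(
    seq: PeptideSequence,
    series: Iterable[str] = ("a", "b", "y"),
    internal: bool = False,
    neutral_losses: Sequence[Formula] = (),
) -> List[FragmentIon]:
    """Peptide b/a/y terminal fragments and optional internal fragments.

    b_i = residues 1..i; a_i = b_i - CO; y_i = residues n-i+1..n + H2O.
    Internal fragments (amide type = residue sum; a type = amide - CO) cover
    every proper interval p..q with 1 < p <= q < n.
    """
    series = [s.lower() for s in series]
    if set(series) - {"a", "b", "y"}:
        raise ValueError("peptide series must be among {'a', 'b', 'y'}")
    n = len(seq)

    def residue_sum(p: int, q: int) -> Formula:
        total = Formula()
        for pos in range(p, q + 1):
            total = total + AMINO_ACID_RESIDUES[seq[pos]]
        return total

    out: List[FragmentIon] = []
    for i in range(1, n):
        b_formula = residue_sum(1, i)
        if "b" in series:
            out.extend(_with_neutral_losses(
                FragmentIon(seq, "terminal5", f"b{i}", 1, i, b_formula, ("b",)),
                neutral_losses,
            ))
        if "a" in series:
            out.extend(_with_neutral_losses(
                FragmentIon(seq, "terminal5", f"a{i}", 1, i, b_formula - CO, ("a",)),
                neutral_losses,
            ))
        if "y" in series:
            out.extend(_with_neutral_losses(
                FragmentIon(
                    seq, "terminal3", f"y{i}", n - i + 1, n,
                    residue_sum(n - i + 1, n) + H2O, ("y",),
                ),
                neutral_losses,
            ))
    if internal:
        for p in range(2, n):
            for q in range(p, n):
                amide = residue_sum(p, q)
                out.append(FragmentIon(
                    seq, "internal", f"int({p}-{q})", p, q, amide, ("b", "y"),
                ))
                out.append(FragmentIon(
                    seq, "internal", f"int({p}-{q})-CO", p, q, amide - CO, ("a", "y"),
                ))
    return out


def fragments_to_tsv(fragments: Sequence[FragmentIon]) -> str:
    """TSV table: label, kind, covered positions, neutral formula, neutral mass."""
    lines = ["label\tkind\tstart\tend\tformula\tneutral_mass"]
    for frag in fragments:
        lines.append(
            f"{frag.label}\t{frag.kind}\t{frag.start}\t{frag.end}\t"
            f"{frag.formula.hill()}\t{frag.neutral_mass:.4f}"
        )
    return "\n".join(lines) + "\n"
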