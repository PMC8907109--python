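"""Elemental-formula arithmetic, monoisotopic masses and isotopologue envelopes.

This module is the mass-math currency of the package.  Two conventions are
fixed here and used everywhere:

* The *principal* isotope of an element is its **most abundant** one, not the
  lightest.  For light elements (C, H, N, O, P, S) the two coincide, but for
  platinum the principal isotope is 195Pt (abundance 0.3378), so a platinated
  formula's "monoisotopic" mass uses 194.9647917 Da for Pt.  This is the
  convention under which negative-mode Orbitrap assignments of platinated
  oligonucleotides reproduce to four decimals.

* Ion m/z is computed with explicit proton *and electron* mass bookkeeping:
  removing an electron per unit of metal cationic charge (Pt(II) contributes
  +2 and two electron masses are subtracted) and transferring protons at
  1.00727646688 Da.  At charge 6- and m/z ~700 the electron term alone is
  ~0.2 mDa per charge and is required to match printed values.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Iterator, Mapping, Tuple

import numpy as np

__all__ = [
    "PROTON_MASS",
    "ELECTRON_MASS",
    "Formula",
    "FormulaError",
    "IsotopePattern",
    "isotope_table",
    "principal_mass",
    "monoisotopic_mass",
    "ion_mz",
    "isotope_pattern",
]

PROTON_MASS = 1.00727646688
ELECTRON_MASS = 0.00054857990


class FormulaError(ValueError):
    """Raised for unparseable formulas or invalid element counts."""


def _load_isotope_table() -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    table: Dict[str, list] = {}
    text = resources.files("adductms.data").joinpath("isotopes.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        element, _massnum, mass, abundance = line.split("\t")
        table.setdefault(element, []).append((float(mass), float(abundance)))
    out: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for element, rows in table.items():
        rows.sort()
        masses = np.array([m for m, _ in rows])
        abund = np.array([a for _, a in rows])
        if not np.isclose(abund.sum(), 1.0, atol=1e-6):
            raise FormulaError(f"isotope abundances for {element} sum to {abund.sum()}")
        out[element] = (masses, abund)
    return out


_ISOTOPES: Dict[str, Tuple[np.ndarray, np.ndarray]] = _load_isotope_table()


def isotope_table() -> Mapping[str, Tuple[np.ndarray, np.ndarray]]:
    """Per-element (masses, abundances) arrays, sorted by mass."""
    return _ISOTOPES


def principal_mass(element: str) -> float:
    """Mass of the element's most abundant isotope."""
    try:
        masses, abund = _ISOTOPES[element]
    except KeyError:
        raise FormulaError(f"unknown element symbol: {element!r}") from None
    return float(masses[int(np.argmax(abund))])


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class Formula(Mapping[str, int]):
    """An element -> count table supporting element-wise arithmetic.

    Counts may go negative in intermediate arithmetic (e.g. the internucleotide
    linkage delta HPO3 - H2O has H: -1); :meth:`require_nonnegative` is the
    finalization check applied before a formula is treated as a real molecule.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None, **kwargs: int):
        merged: Dict[str, int] = {}
        for source in (counts or {}), kwargs:
            for element, n in source.items():
                if element not in _ISOTOPES:
                    raise FormulaError(f"unknown element symbol: {element!r}")
                merged[element] = merged.get(element, 0) + int(n)
        object.__setattr__(self, "_counts", {e: n for e, n in merged.items() if n != 0})

    @classmethod
    def parse(cls, text: str) -> "Formula":
        """Parse a Hill-style concatenation like ``"C126H166N50O75P12Pt"``.

        Multi-letter symbols are matched greedily (``Pt`` wins over ``P``).
        An absent count means 1; an explicit zero or negative count is an error.
        """
        counts: Dict[str, int] = {}
        pos = 0
        stripped = text.strip()
        while pos < len(stripped):
            match = _TOKEN.match(stripped, pos)
            if match is None or not match.group(1):
                raise FormulaError(
                    f"cannot parse formula {text!r} at {stripped[pos:pos + 4]!r}"
                )
            element, digits = match.groups()
            if element not in _ISOTOPES:
                raise FormulaError(f"unknown element symbol: {element!r}")
            if digits == "":
                n = 1
            else:
                n = int(digits)
                if n <= 0:
                    raise FormulaError(f"invalid count {n} for {element} in {text!r}")
            counts[element] = counts.get(element, 0) + n
            pos = match.end()
        return cls(counts)

    # -- Mapping protocol ---------------------------------------------------
    def __getitem__(self, element: str) -> int:
        return self._counts[element]

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def get(self, element: str, default: int = 0) -> int:
        return self._counts.get(element, default)

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other: "Formula") -> "Formula":
        counts = dict(self._counts)
        for element, n in other.items():
            counts[element] = counts.get(element, 0) + n
        return Formula(counts)

    def __sub__(self, other: "Formula") -> "Formula":
        counts = dict(self._counts)
        for element, n in other.items():
            counts[element] = counts.get(element, 0) - n
        return Formula(counts)

    def __mul__(self, n: int) -> "Formula":
        return Formula({e: c * n for e, c in self._counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Formula):
            return NotImplemented
        return self._counts == other._counts

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def __repr__(self) -> str:
        return f"Formula({self.hill()!r})"

    def hill(self) -> str:
        """Hill notation: C, H first, then remaining elements alphabetically."""
        parts = []
        for element in ("C", "H"):
            n = self._counts.get(element, 0)
            if n:
                parts.append(f"{element}{n if n != 1 else ''}")
        for element in sorted(self._counts):
            if element in ("C", "H"):
                continue
            n = self._counts[element]
            parts.append(f"{element}{n if n != 1 else ''}")
        return "".join(parts)

    def require_nonnegative(self) -> "Formula":
        negatives = {e: n for e, n in self._counts.items() if n < 0}
        if negatives:
            raise FormulaError(f"negative element counts: {negatives}")
        return self

    @property
    def monoisotopic_mass(self) -> float:
        return monoisotopic_mass(self)


def monoisotopic_mass(formula: Mapping[str, int]) -> float:
    """Principal-isotope mass: sum of count x most-abundant-isotope mass."""
    return float(sum(n * principal_mass(e) for e, n in formula.items()))


def ion_mz(
    neutral_mass: float,
    electrons_removed: int,
    protons_added: int,
    protons_removed: int,
    z: int,
) -> float:
    """m/z of a charged species with explicit proton/electron bookkeeping.

    ``electrons_removed`` is the total metal cationic charge (2 per Pt(II)).
    The signed charge must balance:
    ``z = electrons_removed + protons_added - protons_removed``.
    """
    if z == 0:
        raise ValueError("|z| must be >= 1")
    if electrons_removed + protons_added - protons_removed != z:
        raise ValueError(
            f"charge balance mismatch: +{electrons_removed} cationic "
            f"+{protons_added}H -{protons_removed}H != z={z:+d}"
        )
    mass = (
        neutral_mass
        - electrons_removed * ELECTRON_MASS
        + (protons_added - protons_removed) * PROTON_MASS
    )
    return mass / abs(z)


@dataclass(frozen=True)
class IsotopePattern:
    """Centroided isotopologue envelope: (mass, relative abundance) pairs.

    Masses are strictly increasing; abundances are positive and sum to 1 up to
    the configured pruning budget.  The same container is used for envelopes
    in neutral-mass space and (after :meth:`to_mz`) in m/z space.
    """

    masses: np.ndarray
    abundances: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "masses", np.asarray(self.masses, dtype=float))
        object.__setattr__(self, "abundances", np.asarray(self.abundances, dtype=float))
        if self.masses.ndim != 1 or self.masses.shape != self.abundances.shape:
            raise ValueError("masses and abundances must be 1-D and equal length")
        if len(self.masses) and np.any(np.diff(self.masses) <= 0):
            raise ValueError("isotopologue masses must be strictly increasing")
        if np.any(self.abundances <= 0):
            raise ValueError("isotopologue abundances must be positive")

    def __len__(self) -> int:
        return len(self.masses)

    @property
    def principal_index(self) -> int:
        """Index of the most abundant isotopologue."""
        return int(np.argmax(self.abundances))

    @property
    def principal_mass(self) -> float:
        return float(self.masses[self.principal_index])

    def aggregate_nominal(self) -> "IsotopePattern":
        """Merge isotopic fine structure into one centroid per nominal
        isotopologue (nucleon-count offset from the lowest-mass peak).

        Centroided Orbitrap data does not resolve the few-mDa splittings
        between e.g. 13C- and 15N-substituted isotopologues, so envelopes
        used for spectrum matching and simulation are aggregated to this
        level; the abundance-weighted centroid of each cluster is kept.
        Only meaningful in neutral-mass (not m/z) space.
        """
        if len(self) < 2:
            return self
        bins = np.rint(self.masses - self.masses[0]).astype(int)
        n_bins = bins.max() + 1
        sums = np.bincount(bins, weights=self.abundances, minlength=n_bins)
        weighted = np.bincount(
            bins, weights=self.abundances * self.masses, minlength=n_bins
        )
        keep = sums > 0
        return IsotopePattern(weighted[keep] / sums[keep], sums[keep])

    def to_mz(
        self,
        electrons_removed: int,
        protons_added: int,
        protons_removed: int,
        z: int,
    ) -> "IsotopePattern":
        """Shift the envelope by the charging deltas and divide by |z|."""
        if z == 0:
            raise ValueError("|z| must be >= 1")
        shift = (
            -electrons_removed * ELECTRON_MASS
            + (protons_added - protons_removed) * PROTON_MASS
        )
        return IsotopePattern((self.masses + shift) / abs(z), self.abundances)


def _merge_centroids(
    masses: np.ndarray, abund: np.ndarray, tol: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Merge peaks closer than ``tol`` Da into abundance-weighted centroids."""
    order = np.argsort(masses, kind="stable")
    masses, abund = masses[order], abund[order]
    if len(masses) < 2:
        return masses, abund
    # group boundaries where the gap to the previous centroid exceeds tol
    group = np.concatenate([[0], np.cumsum(np.diff(masses) > tol)])
    n_groups = group[-1] + 1
    sums = np.bincount(group, weights=abund, minlength=n_groups)
    weighted = np.bincount(group, weights=abund * masses, minlength=n_groups)
    return weighted / sums, sums


def _convolve(
    a: Tuple[np.ndarray, np.ndarray],
    b: Tuple[np.ndarray, np.ndarray],
    merge_tol: float,
    floor: float,
) -> Tuple[np.ndarray, np.ndarray]:
    masses = (a[0][:, None] + b[0][None, :]).ravel()
    abund = (a[1][:, None] * b[1][None, :]).ravel()
    masses, abund = _merge_centroids(masses, abund, merge_tol)
    if floor > 0 and len(abund):
        keep = abund >= floor * abund.max()
        masses, abund = masses[keep], abund[keep]
    return masses, abund


def isotope_pattern(
    formula: Mapping[str, int],
    prune: float = 1e-4,
    merge_tol: float = 1e-3,
) -> IsotopePattern:
    """Isotopologue envelope of a formula by iterative pairwise convolution.

    Per-element distributions are raised to their count by binary
    exponentiation, convolved together, with centroids within ``merge_tol``
    (default 1 mDa, Orbitrap-resolved) merged at every step.  Peaks below
    ``prune`` x the base peak are dropped and the envelope renormalized to
    sum 1.  ``prune=0`` keeps the exact (merged) envelope.
    """
    if not 0 <= prune < 1:
        raise ValueError("prune must be in [0, 1)")
    Formula(dict(formula)).require_nonnegative()
    # a generous intermediate floor keeps envelopes tractable without biasing
    # the final pruning decision
    floor = 0.0 if prune == 0 else prune * 1e-3
    total: Tuple[np.ndarray, np.ndarray] = (np.array([0.0]), np.array([1.0]))
    for element, count in sorted(formula.items()):
        if count == 0:
            continue
        base = _ISOTOPES[element]
        # binary exponentiation: element distribution ** count
        power = base
        remaining = count
        while remaining:
            if remaining & 1:
                total = _convolve(total, power, merge_tol, floor)
            remaining >>= 1
            if remaining:
                power = _convolve(power, power, merge_tol, floor)
    masses, abund = total
    if prune > 0:
        keep = abund >= prune * abund.max()
        masses, abund = masses[keep], abund[keep]
    abund = abund / abund.sum()
    order = np.argsort(masses)
    return IsotopePattern(masses[order], abund[order])
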