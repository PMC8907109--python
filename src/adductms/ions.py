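"""Expansion of neutral fragments into observable charged species.

Metal binding is modeled purely as a formula + cationic-charge delta: a
Pt(II)-containing adduct adds its atoms and removes two electrons; any
covalent proton displacement at the binding site is absorbed into the
species' net proton count, matching the ``[... - 8H]`` bookkeeping used for
negative-mode oligonucleotide assignments.  Alkali exchange (Na+/K+ for H+)
adds the metal atom and one cationic charge and implies at least one proton
removal; the species label counts total protons removed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple, Union

from .chem import Formula, IsotopePattern, ion_mz, isotope_pattern
from .fragments import FragmentIon

__all__ = [
    "Adduct",
    "IonSpecies",
    "BUILTIN_ADDUCTS",
    "NEGATIVE_MODE_ADDUCTS",
    "POSITIVE_MODE_ADDUCTS",
    "build_species",
    "expand_search_space",
    "species_to_tsv",
]

#: elements whose presence in an adduct marks the species as metalated
#: (alkali exchange alone does not count as metalation)
_NON_METAL = {"C", "H", "N", "O", "P", "S", "Se", "Na", "K", "Li", "Rb", "Cs"}


@dataclass(frozen=True)
class Adduct:
    """A named formula/charge delta attached to a species.

    ``cationic_charge`` is the number of electrons removed (2 for Pt(II));
    ``min_proton_exchange`` is the number of protons an attachment displaces
    at minimum (1 for an alkali-for-proton exchange).
    """

    name: str
    formula: Formula
    cationic_charge: int
    min_proton_exchange: int = 0
    max_count: int = 1

    @property
    def is_metal(self) -> bool:
        return any(e not in _NON_METAL for e in self.formula)


BUILTIN_ADDUCTS: Dict[str, Adduct] = {
    a.name: a
    for a in (
        Adduct("Pt", Formula(Pt=1), 2, max_count=3),
        Adduct("Pt(NH3)", Formula(Pt=1, N=1, H=3), 2, max_count=3),
        Adduct("Pt(NH3)2", Formula(Pt=1, N=2, H=6), 2, max_count=3),
        Adduct("Na", Formula(Na=1), 1, min_proton_exchange=1, max_count=3),
        Adduct("K", Formula(K=1), 1, min_proton_exchange=1, max_count=3),
    )
}

#: default adduct menus mirroring cisplatin binding studies
NEGATIVE_MODE_ADDUCTS = [
    BUILTIN_ADDUCTS[name] for name in ("Pt", "Pt(NH3)", "Pt(NH3)2", "Na", "K")
]
POSITIVE_MODE_ADDUCTS = [
    BUILTIN_ADDUCTS[name] for name in ("Pt", "Pt(NH3)", "Pt(NH3)2")
]

#: default |z| ranges per polarity, matching observed species
DEFAULT_CHARGE_RANGE = {"neg": range(1, 7), "pos": range(1, 6)}


@dataclass(frozen=True)
class IonSpecies:
    """A charged, possibly adducted fragment or precursor with its m/z."""

    fragment: FragmentIon
    adducts: Tuple[Tuple[Adduct, int], ...]
    protons_added: int
    protons_removed: int
    z: int
    total_formula: Formula
    mz: float
    label: str

    @property
    def electrons_removed(self) -> int:
        return sum(a.cationic_charge * n for a, n in self.adducts)

    @property
    def is_platinated(self) -> bool:
        """True if the species carries at least one metal-containing adduct."""
        return any(a.is_metal and n > 0 for a, n in self.adducts)

    def envelope(self, prune: float = 1e-4, fine_structure: bool = False) -> IsotopePattern:
        """Isotopologue envelope of the total formula, in m/z space.

        By default fine structure is aggregated to one centroid per nominal
        isotopologue (the level centroided Orbitrap spectra resolve);
        ``fine_structure=True`` keeps the 1 mDa-merged envelope.
        """
        pattern = isotope_pattern(self.total_formula, prune=prune)
        if not fine_structure:
            pattern = pattern.aggregate_nominal()
        return pattern.to_mz(
            self.electrons_removed, self.protons_added, self.protons_removed, self.z
        )

    def _dedup_key(self) -> Tuple[Formula, int, int, int]:
        return (self.total_formula, self.z, self.protons_added, self.protons_removed)


def _species_label(
    fragment: FragmentIon,
    adducts: Sequence[Tuple[Adduct, int]],
    protons_added: int,
    protons_removed: int,
    z: int,
) -> str:
    parts = [fragment.label]
    for adduct, n in adducts:
        if n == 1:
            parts.append(f"+ {adduct.name}")
        elif n > 1:
            parts.append(f"+ {n}{adduct.name}")
    if protons_added:
        parts.append(f"+ {protons_added}H")
    if protons_removed:
        parts.append(f"- {protons_removed}H")
    sign = "-" if z < 0 else "+"
    return f"[{' '.join(parts)}]{abs(z)}{sign}"


def build_species(
    fragment: FragmentIon,
    adducts: Union[Mapping[Adduct, int], Sequence[Tuple[Adduct, int]]] = (),
    protons_added: int = 0,
    protons_removed: int = 0,
) -> IonSpecies:
    """Attach adducts and proton transfers to a neutral fragment.

    The signed charge is ``z = sum(cationic charges) + protons_added -
    protons_removed`` and must be nonzero; the total formula (fragment +
    adduct atoms) must have no negative element count.
    """
    if isinstance(adducts, Mapping):
        adduct_items = tuple((a, int(n)) for a, n in adducts.items() if n)
    else:
        adduct_items = tuple((a, int(n)) for a, n in adducts if n)
    cationic = sum(a.cationic_charge * n for a, n in adduct_items)
    z = cationic + protons_added - protons_removed
    if z == 0:
        raise ValueError(
            f"species {fragment.label} with {cationic:+d} cationic, "
            f"+{protons_added}H, -{protons_removed}H has zero net charge"
        )
    total = fragment.formula
    for adduct, n in adduct_items:
        total = total + adduct.formula * n
    total.require_nonnegative()
    mz = ion_mz(
        total.monoisotopic_mass, cationic, protons_added, protons_removed, z
    )
    return IonSpecies(
        fragment=fragment,
        adducts=adduct_items,
        protons_added=protons_added,
        protons_removed=protons_removed,
        z=z,
        total_formula=total,
        mz=mz,
        label=_species_label(fragment, adduct_items, protons_added, protons_removed, z),
    )


def expand_search_space(
    fragments: Sequence[FragmentIon],
    adducts: Sequence[Adduct] = (),
    charges: Iterable[int] = range(1, 7),
    polarity: str = "neg",
    cap: int = 500_000,
    strict: bool = False,
) -> List[IonSpecies]:
    """Cartesian expansion fragment x adduct multiset x charge state.

    Each adduct contributes 0..max_count copies.  In negative mode a species
    at |z| = k removes ``cationic + k`` protons; in positive mode protons are
    added (or removed, if the cationic charge exceeds k) to reach +k.
    Duplicate (formula, z, proton bookkeeping) combinations collapse to one
    species; output is sorted by (m/z, label).  More than ``cap`` candidate
    species raises in strict mode, otherwise warns and truncates.
    """
    if polarity not in ("neg", "pos"):
        raise ValueError("polarity must be 'neg' or 'pos'")
    if cap <= 0:
        raise ValueError("cap must be positive")
    charges = [abs(int(k)) for k in charges]
    if any(k < 1 for k in charges):
        raise ValueError("charge magnitudes must be >= 1")
    count_ranges = [range(a.max_count + 1) for a in adducts]
    seen = {}
    total_combos = 0
    for counts in itertools.product(*count_ranges):
        combo = tuple((a, n) for a, n in zip(adducts, counts) if n)
        cationic = sum(a.cationic_charge * n for a, n in combo)
        min_exchange = sum(a.min_proton_exchange * n for a, n in combo)
        for fragment in fragments:
            for k in charges:
                if polarity == "neg":
                    pa, pr = 0, cationic + k
                else:
                    if k >= cationic:
                        pa, pr = k - cationic + min_exchange, min_exchange
                    else:
                        pa, pr = 0, cationic - k
                    if pr < min_exchange:
                        pa, pr = pa + (min_exchange - pr), min_exchange
                try:
                    species = build_species(fragment, combo, pa, pr)
                except ValueError:
                    continue
                total_combos += 1
                seen.setdefault(species._dedup_key(), species)
    out = sorted(seen.values(), key=lambda s: (s.mz, s.label))
    if len(out) > cap:
        if strict:
            raise ValueError(
                f"search space of {len(out)} species (from {total_combos} "
                f"combinations) exceeds cap {cap}"
            )
        warnings.warn(
            f"search space truncated from {len(out)} to {cap} species",
            stacklevel=2,
        )
        out = out[:cap]
    return out


def species_to_tsv(species: Sequence[IonSpecies]) -> str:
    """TSV table: label, formula, z, theoretical m/z."""
    lines = ["label\tformula\tz\tmz"]
    for s in species:
        lines.append(f"{s.label}\t{s.total_formula.hill()}\t{s.z:+d}\t{s.mz:.4f}")
    return "\n".join(lines) + "\n"
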