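"""Formula parsing, monoisotopic masses, m/z bookkeeping and envelopes."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from adductms.chem import (
    ELECTRON_MASS,
    PROTON_MASS,
    Formula,
    FormulaError,
    ion_mz,
    isotope_pattern,
    isotope_table,
    monoisotopic_mass,
)

ELEMENTS = ["C", "H", "N", "O", "P", "S"]
small_formula = st.fixed_dictionaries(
    {}, optional={e: st.integers(1, 8) for e in ELEMENTS}
).filter(lambda d: d)


class TestParse:
    def test_water(self):
        assert dict(Formula.parse("H2O")) == {"H": 2, "O": 1}

    def test_platinated_oligo_formula(self):
        f = Formula.parse("C126H166N50O75P12Pt")
        assert dict(f) == {"C": 126, "H": 166, "N": 50, "O": 75, "P": 12, "Pt": 1}

    def test_implicit_count_is_one(self):
        assert Formula.parse("CHNOPS")["S"] == 1

    def test_greedy_multiletter_symbol(self):
        # Pt wins over P + invalid 't'
        assert Formula.parse("PtP2")["Pt"] == 1
        assert Formula.parse("PtP2")["P"] == 2

    @pytest.mark.parametrize("bad", ["Xx3", "c2", "H0", "H-2", "Q5"])
    def test_invalid_tokens_rejected(self, bad):
        with pytest.raises(FormulaError):
            Formula.parse(bad)

    def test_error_names_offending_token(self):
        with pytest.raises(FormulaError, match="Xx"):
            Formula.parse("Xx3")


class TestArithmetic:
    def test_elementwise_add_sub(self):
        assert Formula(H=2, O=1) + Formula(H=1) == Formula(H=3, O=1)
        assert Formula(H=2, O=1) - Formula(H=2) == Formula(O=1)

    def test_intermediate_negatives_allowed_but_finalization_rejects(self):
        linkage = Formula(H=1, P=1, O=3) - Formula(H=2, O=1)
        assert linkage["H"] == -1
        with pytest.raises(FormulaError):
            linkage.require_nonnegative()

    @given(small_formula, small_formula)
    def test_mass_is_additive(self, a, b):
        fa, fb = Formula(a), Formula(b)
        assert monoisotopic_mass(fa + fb) == pytest.approx(
            monoisotopic_mass(fa) + monoisotopic_mass(fb), abs=1e-12
        )


class TestMonoisotopicMass:
    def test_water(self):
        assert monoisotopic_mass(Formula(H=2, O=1)) == pytest.approx(18.010565, abs=1e-6)

    def test_empty_formula_has_zero_mass(self):
        assert monoisotopic_mass(Formula()) == 0.0

    def test_principal_isotope_is_most_abundant_not_lightest(self):
        # the platinated-oligo formula mass only comes out right with 195Pt
        f = Formula.parse("C126H166N50O75P12Pt")
        assert monoisotopic_mass(f) == pytest.approx(4145.7212, abs=5e-4)
        assert monoisotopic_mass(Formula(Pt=1)) == pytest.approx(194.964792, abs=1e-5)


class TestIonMz:
    @pytest.mark.parametrize(
        "mass,er,pa,pr,z,expected",
        [
            (4145.7212, 2, 0, 5, -3, 1380.2279),  # platinated strand, 3-
            (4674.7577, 6, 0, 9, -3, 1555.2296),  # tris-platinated strand, 3-
            (18.010565, 0, 1, 0, 1, 19.018290),   # protonated water
        ],
    )
    def test_charged_species_mz(self, mass, er, pa, pr, z, expected):
        assert ion_mz(mass, er, pa, pr, z) == pytest.approx(expected, abs=5e-4)

    def test_deprotonation_identity(self):
        mass = 1000.0
        assert ion_mz(mass, 0, 0, 1, -1) == pytest.approx(mass - 1.0072765, abs=1e-6)

    def test_charge_balance_mismatch_rejected(self):
        with pytest.raises(ValueError, match="balance"):
            ion_mz(1000.0, 2, 0, 5, -4)

    def test_zero_charge_rejected(self):
        with pytest.raises(ValueError):
            ion_mz(1000.0, 0, 0, 0, 0)

    def test_electron_mass_accounting(self):
        with_e = ion_mz(1000.0, 2, 0, 4, -2)
        naive = (1000.0 - 4 * PROTON_MASS) / 2
        assert with_e == pytest.approx(naive - ELECTRON_MASS, abs=1e-9)


def _nominal_clusters(masses, abund, ref):
    """Aggregate a centroid list into nominal-isotopologue cluster sums."""
    bins = np.rint(np.asarray(masses) - ref).astype(int)
    abund = np.asarray(abund)
    sums = np.zeros(bins.max() + 1)
    np.add.at(sums, bins, abund)
    centroids = np.zeros_like(sums)
    np.add.at(centroids, bins, abund * np.asarray(masses))
    keep = sums > 0
    return centroids[keep] / sums[keep], sums[keep]


class TestIsotopePattern:
    def test_platinum_envelope_is_table_lookup(self):
        pat = isotope_pattern(Formula(Pt=1), prune=0)
        assert len(pat) == 6
        assert pat.principal_mass == pytest.approx(194.9648, abs=1e-4)
        assert pat.abundances.max() == pytest.approx(0.338, abs=1e-3)

    def test_c100_ratio_matches_binomial_closed_form(self):
        pat = isotope_pattern(Formula(C=100), prune=0)
        ratio = pat.abundances[1] / pat.abundances[0]
        assert ratio == pytest.approx(100 * 0.0107 / 0.9893, rel=1e-9)

    @given(small_formula)
    def test_normalization_invariant(self, counts):
        pat = isotope_pattern(Formula(counts), prune=1e-4)
        assert pat.abundances.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(pat.abundances > 0)
        assert np.all(np.diff(pat.masses) > 0)

    @given(small_formula, small_formula)
    def test_convolution_oracle_equivalence(self, a, b):
        """pattern(f1 + f2) equals the brute-force outer-product convolution
        of pattern(f1) and pattern(f2), cluster by nominal isotopologue."""
        fa, fb = Formula(a), Formula(b)
        combined = isotope_pattern(fa + fb, prune=0)
        pa = isotope_pattern(fa, prune=0)
        pb = isotope_pattern(fb, prune=0)
        brute_m = (pa.masses[:, None] + pb.masses[None, :]).ravel()
        brute_a = (pa.abundances[:, None] * pb.abundances[None, :]).ravel()
        ref = combined.masses[0]
        bm, ba = _nominal_clusters(brute_m, brute_a, ref)
        cm, ca = _nominal_clusters(combined.masses, combined.abundances, ref)
        n = min(len(ba), len(ca))
        keep = ba[:n] > 1e-9
        assert np.allclose(ba[:n][keep], ca[:n][keep], rtol=1e-6)
        assert np.allclose(bm[:n][keep], cm[:n][keep], atol=1e-3)

    def test_platinated_organic_base_peak_is_not_lowest_mass(self):
        pat = isotope_pattern(Formula.parse("C20H30O10Pt"), prune=1e-4)
        assert pat.principal_index > 0

    def test_matches_pyteomics_fine_structure_oracle(self):
        # independent envelope oracle: enumerate isotopologues with pyteomics
        # and compare nominal-cluster abundances and centroids
        from pyteomics import mass as pmass

        comp = pmass.Composition(formula="C10H13N5O3")  # deoxyadenosine
        oracle_m, oracle_a = [], []
        for iso, abundance in pmass.isotopologues(
            composition=comp,
            report_abundance=True,
            overall_threshold=1e-9,
            isotope_threshold=1e-9,  # include 2H and 17O variants too
        ):
            oracle_m.append(pmass.calculate_mass(composition=iso))
            oracle_a.append(abundance)
        pat = isotope_pattern(Formula.parse("C10H13N5O3"), prune=1e-7)
        ref = pat.masses[0]
        om, oa = _nominal_clusters(oracle_m, oracle_a, ref)
        pm, pa = _nominal_clusters(pat.masses, pat.abundances, ref)
        n = min(4, len(om), len(pm))  # clusters with full oracle coverage
        assert np.allclose(oa[:n], pa[:n], rtol=1e-3)
        assert np.allclose(om[:n], pm[:n], atol=1e-3)

    def test_isotope_table_abundances_sum_to_one(self):
        for element, (masses, abund) in isotope_table().items():
            assert abund.sum() == pytest.approx(1.0, abs=1e-6), element
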