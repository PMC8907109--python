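"""Compute m/z of platinated oligonucleotide precursor species.

Builds the 13-mer duplex strands S1/S1c, attaches a cisplatin-derived
Pt(NH3)2(2+) adduct and prints the negative-mode m/z of the species observed
in full-scan ESI-MS.  The electron-mass bookkeeping matters: at charge 6-
dropping it would shift the value by ~0.2 mDa per charge.
"""

from adductms import BUILTIN_ADDUCTS, OligoSequence, build_species
from adductms.fragments import precursor

s1 = OligoSequence("GTATTGGCACGTA", name="S1")
s1c = OligoSequence("TACGTGCCAATAC", name="S1c")
pt_nh3_2 = BUILTIN_ADDUCTS["Pt(NH3)2"]
pt = BUILTIN_ADDUCTS["Pt"]
k = BUILTIN_ADDUCTS["K"]

for strand in (s1, s1c):
    species = build_species(precursor(strand), {pt_nh3_2: 1}, protons_removed=8)
    print(f"{species.label:34s} m/z {species.mz:10.4f}")

# an alkali-exchanged platinated strand seen in adduct-transfer experiments
species = build_species(precursor(s1), [(pt, 1), (k, 2)], protons_removed=7)
print(f"{species.label:34s} m/z {species.mz:10.4f}")

print()
print("Each line is a singly platinated (or K-exchanged) intact strand;")
print("the m/z values are what the instrument shows for these charge states.")
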