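"""Platinated b/y fragments of histone-derived peptides.

P1 comes from the H2A acidic patch and P2 from the H2B alpha-2 helix.
The script prints the positive-mode m/z of the smallest platinated b-ion,
a platinated y-ion, and the intact P2 mono-/bis-platinum species.
"""

from adductms import BUILTIN_ADDUCTS, PeptideSequence, build_species
from adductms.fragments import enumerate_peptide, precursor

p1 = PeptideSequence("VLEYLTAEILE", name="P1")
p2 = PeptideSequence("SKAMGIMNSFVNDIFERIAGEASRLAHY", name="P2")
pt = BUILTIN_ADDUCTS["Pt"]
pt_nh3 = BUILTIN_ADDUCTS["Pt(NH3)"]
pt_nh3_2 = BUILTIN_ADDUCTS["Pt(NH3)2"]

frags = {f.label: f for f in enumerate_peptide(p1, ["a", "b", "y"])}
for frag_label, adduct, removed in (("b2", pt_nh3, 1), ("y4", pt_nh3_2, 1)):
    species = build_species(frags[frag_label], {adduct: 1}, protons_removed=removed)
    print(f"{species.label:26s} m/z {species.mz:9.4f}")

for adducts, added in (({pt: 1}, 2), ({pt_nh3: 2}, 0)):
    species = build_species(precursor(p2), adducts, protons_added=added)
    print(f"{species.label:26s} m/z {species.mz:9.4f}")

print()
print("The small platinated b-ions place the platinum near the N-terminus of")
print("P1; the intact P2 species show mono- and bis-platinum loading.")
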