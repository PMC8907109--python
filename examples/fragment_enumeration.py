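"""Enumerate CID fragments of an oligonucleotide, including internal ions.

Prints the a/w terminal ladder counts for S1c, then the double-cleavage
internal fragments (with base loss at the 3'-side cleavage) whose m/z values
localize metal-free regions of the strand.
"""

from adductms import OligoSequence, build_species
from adductms.fragments import enumerate_oligo_internal, enumerate_oligo_terminal

s1c = OligoSequence("TACGTGCCAATAC", name="S1c")

terminal = enumerate_oligo_terminal(s1c, "abcdwxyz")
print(f"{len(terminal)} terminal fragments (8 series x {len(s1c) - 1} cleavage sites)")

internal = {
    f.label: f
    for f in enumerate_oligo_internal(s1c, ["w"], ["a"], base_loss="at-3'-cleavage")
}
print(f"{len(internal)} internal w:a fragments (with and without base loss)\n")

for label, protons_removed in (("w7:a8-B", 1), ("w10:a9-B", 2), ("w7:a12-B", 2)):
    frag = internal[label]
    species = build_species(frag, {}, protons_removed=protons_removed)
    print(
        f"{species.label:22s} covers positions {frag.start}-{frag.end}  "
        f"m/z {species.mz:9.4f}"
    )

print()
print("These metal-free internal ions all start after the GTG platination")
print("site: cleavage concentrates outside the platinated region.")
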