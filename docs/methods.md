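# Methods

## Mass model

All mass arithmetic runs over element→count tables (`adductms.chem.Formula`)
with an isotope table shipped as plain text (`src/adductms/data/isotopes.tsv`,
NIST-consistent masses and abundances) so every number is auditable.

The *principal isotope* of an element is its most abundant one.  For C, H,
N, O, P and S this coincides with the lightest isotope; for platinum it is
¹⁹⁵Pt (194.9647917 Da, abundance 0.33832).  This convention is what makes
"monoisotopic" masses of platinated species agree with negative-mode
Orbitrap assignments to four decimals; using ¹⁹⁰Pt or ¹⁹⁴Pt shifts intact
13-mer species by whole m/z units at low charge.

Ion m/z is computed as

    m/z = (M − e·mₑ + (p₊ − p₋)·m_p) / |z|,    z = e + p₊ − p₋ (signed)

with explicit electron masses (mₑ = 0.00054857990 Da) subtracted per unit of
metal cationic charge and proton transfers at m_p = 1.00727646688 Da.  The
electron term is ~0.55 mDa per Pt(II) and is required to stay inside a
±0.0005 window on formula-derived values.  Charge balance is validated: a
species whose stated proton/electron counts do not produce its charge is
rejected rather than silently fixed.

## Isotopologue envelopes

Envelopes are computed by iterative pairwise convolution of per-element
isotope distributions, using binary exponentiation for element powers.
Centroids closer than 1 mDa are merged (abundance-weighted) at every step;
peaks below `prune` × base peak (default 10⁻⁴) are dropped and the envelope
renormalized to unit sum.  `prune=0` keeps the exact merged envelope.

At 1 mDa the envelope still separates isotopic *fine structure* — e.g. the
¹³C- and ¹⁵N-substituted isotopologues of an oligonucleotide are ~6 mDa
apart.  A 120k-resolution Orbitrap does not resolve this splitting in
centroided data (FWHM ≈ 35 mDa at 4200 Da), so ion-species envelopes used
for matching and simulation are aggregated to one abundance-weighted
centroid per nominal isotopologue (`IsotopePattern.aggregate_nominal`);
`fine_structure=True` exposes the unaggregated envelope.  Aggregation is
what makes the envelope spacing ≈ 1.00336/|z| for CHNOP species and keeps
greedy peak assignment stable under ppm-scale jitter.

## Fragment chemistry

With fragments built as Σ nucleosides + (k−1) × linkage (linkage =
HPO₃ − H₂O), the end-group deltas are a: −H₂O, b: 0, c: +HPO₃−H₂O, d: +HPO₃
on the 3′ cut end and w: +HPO₃, x: +HPO₃−H₂O, y: 0, z: −H₂O on the 5′ cut
end, so each complementary pair (a/w, b/x, c/y, d/z) sums exactly to the
neutral strand.  Synthetic-oligo termini default to 5′-OH/3′-OH — the
convention under which intact-strand assignments reproduce — with terminal
phosphates configurable per end.

Base-loss ("-B") fragments lose the neutral base (BH) of the residue at the
fragment's 3′-side cleavage position: position *i* for a 5′-series fragment
aᵢ, position *q* for an internal fragment covering p..q.  This choice is
decisive — it reproduces the assigned internal-fragment m/z values exactly —
and an "any internal base" mode exists but is off by default.  Exotic
neutral-loss channels (water, ammonia, or user-supplied deltas such as CH₂)
are optional per-fragment variants, default-disabled.

Internal oligonucleotide fragments pair one 3′ series with one 5′ series
over every proper overlap 1 < p ≤ q < n; labels are case-normalized
(`w7:a8-B`).  Peptides produce b/a/y ions and, optionally, amide- and
a-type internal fragments.  Intact strands/peptides flow through the same
`FragmentIon` record with kind `precursor`, so survey (full-scan) and MS/MS
matching share one code path.

Known irreproducible assignments: one reported a-B terminal-fragment value
for this system (913.1376 for a hexamer with guanine loss) is ~18 Da/charge
from any construction this model admits and is flagged rather than forced;
where a reported species label's proton/charge count is inconsistent with
the m/z it accompanies, the m/z-consistent interpretation is used.

## Ion species and search-space expansion

Adducts are (name, formula delta, cationic charge) records; built-ins cover
Pt, Pt(NH₃), Pt(NH₃)₂ (all +2) and Na/K-for-H exchange (+1, implying at
least one proton removal).  "Platinated" means carrying ≥ 1 metal adduct;
alkali exchange alone does not count.  Expansion takes the Cartesian
product fragment × adduct multiset (0..3 per adduct by default) × charge
state (1–6 negative for oligos, 1–5 positive for peptides), removes
duplicate (formula, charge, proton-bookkeeping) species, orders by m/z and
truncates at a configurable cap with a warning (or an error in strict
mode).  Coordination chemistry is deliberately not modeled: a metal adduct
is a composition and charge delta, nothing more.

## Spectrum matching

Theoretical isotopologues are assigned, most abundant first, to the nearest
unused peak within the ppm tolerance (default 5 ppm, consistent with the
~1–3 ppm errors of Orbitrap assignments).  The similarity score is the
total-variation overlap of the unit-normalized theoretical and matched
intensity vectors: bounded in [0, 1], invariant to uniform intensity
scaling, 1 exactly when shapes agree.  Total-variation overlap is this
package's choice of metric (no standard definition exists for this kind of
envelope score); cosine similarity is available behind a switch, and the
0.75 threshold is a configurable filter rather than a hard-coded cut
(0.90 is the customary survey-mode setting).  A match additionally requires
the principal isotopologue to be matched.  Peaks may serve multiple species
(isobars are expected); species whose principal m/z values lie within the
tolerance of each other share an isobar-group id in the output.

Monotonicity caveat: enlarging the tolerance cannot unmatch a previously
matched isotopologue, but on adversarial spectra a newly captured noise
peak can lower the renormalized score.  The monotonicity property is
guaranteed — and tested — on planted synthetic spectra where added matches
are true envelope peaks.

## Synthetic spectra

No raw platination spectra are publicly deposited, so the matcher and the
reporting layer are validated on seeded synthetic spectra
(`adductms.simulate`): each planted species contributes its aggregated
envelope with multiplicative Gaussian m/z jitter (σ in ppm; 2 ppm is the
standard test condition, matching Orbitrap calibration drift), log-normal
multiplicative intensity noise (σ = 0.2 in the standard condition), plus
uniform-m/z, exponential-intensity decoy peaks (50 in the standard
condition).  A fixed seed makes output fully deterministic, and the
generator writes the same two-column text dialect the reader consumes
(round-trips bit-identically, via `repr` formatting).

What the generator does *not* emulate: peak-shape/profile effects,
centroiding artifacts, charge-state-dependent intensity response,
chromatographic dimension, in-source fragmentation, and real chemical noise
structure.  Passing the recovery tests therefore demonstrates correctness
of enumeration, envelope prediction and scoring under realistic mass error
— not robustness to every artifact of real data.

## Reporting

Fragment maps aggregate matches into one track per unique (fragment,
platinated) pair — collapsing charge states and adduct stoichiometries —
with the mean similarity across its ions; per-position summaries count
tracks covering each position, split by platination.  Region classification
follows fragment topology: 5′-terminal series → "5′-end", 3′-terminal →
"3′-end", internal → "Middle" (for peptides: a/b → N-terminal class,
y → C-terminal), with percentages computed separately over the platinated
and metal-free evidence sets; unique species are counted by default
(`count_all=True` counts every ion), and empty evidence sets are flagged
rather than divided by zero.  Residue histograms count every matched
terminal/internal fragment covering each position.  Maps render to SVG with
the customary shading convention (solid ≥ 0.90 mean similarity, faded
below); precursor matches are excluded from all three summaries since they
localize nothing.

## Problem sizes and defaults

Default envelope prune 10⁻⁴ (10⁻³ in matching/simulation, where decade-deep
tails are below noise); merge width 1 mDa; ppm tolerance 5; similarity
threshold 0.75 (0.90 survey); charge ranges 1–6 (negative) and 1–5
(positive); adduct counts 0..3.  The test suite exercises 13-mer strands
and 11/28-residue peptides — the scale the method targets — with property
suites over random sequences up to 20-mers and a 10-species/50-decoy
planted-recovery benchmark; the whole suite runs in seconds on one core.
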