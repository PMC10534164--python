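# Methods

## Chemistry model

All arithmetic is monoisotopic, singly charged (MALDI convention), and
tolerance-based — computed masses are never compared as strings.

A peptide's neutral mass is the sum of its residue masses (standard
monoisotopic table), plus H₂O, plus terminal deltas (N-acetyl +42.010565,
C-amide −0.984016), plus side-chain protection deltas (guanidino NO₂
+44.985078), plus modification deltas. Modifications are an ordered list of
(site, name) pairs; mass is order-independent and each is validated against
the residue and its prior state:

| modification | Δ (Da) | applies to |
|---|---|---|
| `arg_deprotect_deltaOH` | −86.022861 | NO₂-protected Arg (loses CH₂N₄O₂, gains O) |
| `ser_acetyl` | +42.010565 | Ser |
| `dha_from_ser` | −18.010565 | Ser (not acetylated) |
| `dha_from_cys` | −33.987721 | Cys |
| `dha_from_deprotected_arg` | −18.010565 | Arg, after deprotection |

A dehydroalanine (DHA) conversion consumes its site: no second elimination,
no subsequent acetylation. The −86.023 deprotection delta is the net
formula change −CH₂N₄O₂ +O; it is the reading that reproduces the observed
modified-peptide ions (601.39, 583.39, 565.37) to ≤0.03 Da, whereas a
literal "side chain replaced by OH" (−85.015) does not. The constant is
overridable by editing the modification registry.

Crosslink deltas relative to the two intact peptides: disulfide −2H
(−2.015650); lanthionine and Cys-derived lysinoalanine −H₂S (−33.987721);
Ser- or hydroxyl-arginine-derived lysinoalanine −H₂O. The DHA-addition step
is mass-neutral, so β-elimination carries the whole delta — which is why
Cys-derived LAL and lanthionine are exactly isobaric, and why a LAL species
with a spare-Cys DHA sits exactly one H₂S below the lanthionine homopair.

Terminal conventions of the shipped model peptides: Ac-LLSLR-NH₂ with
Arg(NO₂), Ac-LLKLF-NH₂, and Ac-LKDECFR with a free-acid C-terminus and no
arginine protection in crosslinked species — the composition that
reproduces all identified crosslink masses (1901.89, 1869.92, 1835.93,
1591.92). Every convention is per-peptide overridable in the definition
file.

## Candidate enumeration

For each input peptide, all legal concurrent-modification states are
enumerated (site-wise modification stacks, capped at 3 per peptide — the
deepest observed stack is Arg-deprotection plus two DHA). Crosslink species
are then formed over ordered (donor variant, acceptor variant) pairs, all
link types, all donor sites (intact Cys, non-acetylated Ser, deprotected
Arg) and acceptor sites (Lys for LAL, intact Cys otherwise), with total
non-bridge modifications capped at 2 per species. Disulfide and lanthionine
bridges are symmetric molecules, so (A,B)/(B,A) duplicates are collapsed;
lysinoalanine keeps distinct donor/acceptor roles. Intra-peptide (loop)
crosslinks are not enumerated. Isobaric records (equal [M+H]⁺ to 1 μDa) are
retained as distinct entries with mutual cross-references — the basis of
the LAL/lanthionine disambiguation and of site-variant localization.
Queries are binary-search over the m/z-sorted index, nearest-Δ first, ties
broken by annotation for determinism.

## Fragment ions

b/y ions use the standard conventions (bₖ = Σ residues 1..k + N-terminal
delta + proton; yₖ = Σ residues n−k+1..n + H₂O + C-terminal delta +
proton), with protections and modifications riding on their residues. For
crosslinked species, any fragment covering the bridge site carries the full
partner chain plus the link delta; other fragments are plain.

The LAL α–β cleavage pair: fragment **i** is the donor chain in its bridged
state minus the CH₂ that departs with the partner, plus the two hydrogens
restored on cleavage (for Cys and Ser donors this is exactly "crosslink
residue replaced by glycine"; the general form also conserves mass for the
modified-arginine donor, whose site carries the −86.023 delta). Fragment
**ii** is the acceptor chain with an extra CH₂ on the lysine ε-amine.
Because MALDI CID mixes even-electron and radical channels, candidates are
emitted for each plausible H bookkeeping — i at canonical ±1.00783, ii at
M+CH₂ and M+CH₂−H, each also protonated — labeled by variant, and the
matcher takes the nearest: the two characterized spectra themselves differ
by ~1 Da in which ii variant they show, and the 0.8 Da MS/MS tolerance
cannot absorb a 1.008 Da convention error. Canonical pairing conserves mass
to within 2×H of the precursor.

Disulfide triplet marker ions follow the standard pattern around each
chain's protonated thiol form: −33.988 (DHA form), 0, +31.972 (persulfide),
a constant 65.960 Da span. The companion satellite of a LAL species is the
precursor minus H₂S (spare Cys) or minus H₂O (spare, unmodified Ser); a
lanthionine bridge leaves no free thiol, so its absence of a companion is
what the disambiguation rule exploits. Neutral-loss satellites (−H₂O,
−NH₃) are not generated.

## Matching rules

MS tolerance 0.2 Da, MS/MS tolerance 0.8 Da (the instrument-method
defaults; both configurable). Ion-to-peak assignment is greedy by |Δ|, ties
broken by ion-class priority (b/y before diagnostic before marker ions)
then annotation; each experimental peak is evidence for at most one
theoretical ion. Confirmation requires matched distinct b/y ions ≥ the
length of the shorter constituent peptide, counting both chains'
series — the most permissive reading of "at least *x*". Intensity plays no
role in identification. Lanthionine is never positively confirmed: without
a companion peak a hit stays "ambiguous", and only when an MS/MS spectrum
also lacks the diagnostic pair is it downgraded to
"lanthionine-consistent". A species qualifies only when confirmed in every
replicate of its condition.

## Trends

No internal standard exists, so only within-spectrum TIC-normalized
intensities are reported, never absolute quantities (raw intensities are
carried alongside for inspection only). Trend direction is the Spearman
rank correlation of replicate-averaged normalized intensity against the
condition level — a deliberate quantification of trends the source study
reports qualitatively; a rank statistic was chosen over a regression slope
because the intensities are ordinal at best. 3 h is encoded as 0.125 days
for axis ordering. Note that with five levels, ρ of a flat (pure-noise)
profile has a standard deviation near 0.5: single-run ρ values are noisy,
and only aggregates or planted monotone profiles are meaningful.

## Synthetic spectra

The generator plants theoretical peaks with Gaussian m/z jitter (default
σ = 0.05 Da, a quarter of the MS tolerance — errors large enough to make
recovery nontrivial, small enough to be realistic for a calibrated
reflectron TOF), lognormal arbitrary-unit intensities (CV 20%), and
uniform-random noise peaks at 20% of the planted count, within the 700–3000
m/z acquisition window. It emulates centroided peak lists only: no isotope
envelopes, detector saturation, matrix clusters, or ionization-efficiency
model. Passing recovery tests therefore demonstrates the correctness of the
matching logic under calibrated-instrument noise, not robustness to
real-spectrum artifacts such as overlapping isotope distributions or
chimeric precursors.

Validation experiments (`lalms.validation`) run the complete pipeline on
duplicate synthetic spectra of the five identified crosslink species:
100 seeded recovery runs (exact qualified-set equality, compared at
1-decimal precursor m/z since isobaric twins are inseparable by design),
100 seeded trend-sign runs (LAL rising, disulfide falling over heating
time), and an end-to-end reproduction of the reported pH × days detection
grid. Problem sizes (5 species, 2 replicates, 5×5 condition grid) mirror
the study design.

## Numerical choices and edge cases

- Site indices 0-based internally, 1-based in files and reports.
- Masses reported to 3 decimals; all comparisons tolerance-based.
- `query` returns an empty list rather than erroring on no match; an
  all-zero spectrum cannot be TIC-normalized (error).
- Unknown residues, out-of-range sites and chemically impossible
  modifications raise immediately, never yield a silent zero.
- Sodium adducts are generated only as optional satellite candidates
  ([M+Na]⁺ = M + 22.989218) and are never required for identification;
  the observed sodium-adduct spacings of the source spectra are internally
  inconsistent at the 1 Da level and are not asserted anywhere.
- Two printed internal fragments of the characterized spectra (i-y₄
  416.822 and ii-b₄ 522.647) imply an H bookkeeping irreconcilable with
  any single convention; they match under the 0.8 Da MS/MS tolerance but
  are excluded from exact-reproduction tests.

## Known limitations

Proteome-scale search, decoy/FDR machinery, multiply charged ions, average
masses, isotope envelopes, a/c/x/z ions, intensity prediction and
collision-energy modeling are out of scope. The ε-C–N cleavage chemistry
reported for ESI-HCD instruments is a possible extension, not implemented.
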