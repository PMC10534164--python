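# lalms

Identification and localization of **lysinoalanine (LAL)**, **lanthionine**
and **disulfide** crosslinks in MALDI-TOF / TOF-TOF peak lists of model
peptides.

Lysinoalanine is an undesirable protein–protein crosslink that forms in
foods under heat and alkaline conditions (noodles, pretzels, cheeses, milk
products, infant formula). It reduces nutritional value by consuming
lysine, yet no automated way of locating it in mass-spectrometry data
exists: its mass shift is sequence-dependent, it is isobaric with
lanthionine when cysteine-derived, and the candidate space grows as
(*n*² + *n*)/2 pairs for *n* peptides. This package implements, as a
reusable library and CLI, the identification workflow worked out on three
synthetic model peptides — Ac-LLSLR-NH₂ (Arg side chain NO₂-protected),
Ac-LLKLF-NH₂ and Ac-LKDECFR:

1. **Candidate enumeration** — every crosslinked species (disulfide,
   lanthionine, LAL) over every peptide pair, donor/acceptor site and
   concurrent-modification state (arginine deprotection −86.023 Da, serine
   acetylation +42.011, dehydroalanine from Ser −H₂O or Cys −H₂S), indexed
   by [M+H]⁺.
2. **Precursor matching** — MS peaks vs the database at ±0.2 Da.
3. **Sequence confirmation** — a species is confirmed when at least *x*
   distinct b/y ions (plain or with the intact bridge and partner chain
   attached) match the MS/MS spectrum at ±0.8 Da, where *x* is the length
   of the shorter constituent peptide.
4. **LAL vs lanthionine disambiguation** — both crosslinks lose one H₂S
   and are isobaric, but only a LAL-linked pair retains a spare cysteine
   that can eliminate to dehydroalanine, producing a companion peak
   Δ33.99 Da below the precursor. Companion present ⇒ LAL.
5. **Diagnostic ion pair** — cleavage between the α- and β-carbon of the
   LAL bridge gives fragment **i** (donor chain with the crosslink residue
   reduced to glycine) and fragment **ii** (acceptor chain with an extra
   CH₂ on the lysine ε-amine), with ±H transfer variants.
6. **Site localization** — intact-bridge fragments unique to one site
   variant resolve e.g. the Ser-site vs modified-Arg-site ambiguity of
   LL**S**LR(mod)–LL**K**LF.
7. **Replication and trends** — species must be confirmed in both
   duplicates to qualify; TIC-normalized intensities are tracked across pH
   (6–12) and heating time (3 h – 12 days) and summarized by a Spearman
   direction statistic.

A seeded synthetic-spectrum generator (`lalms.synth`) provides
ground-truthed MS/MS/MS peak lists, so the entire workflow is testable
without instrument data.

## Worked example

Simulate spectra of all enumerable crosslink species, then identify the
LAL homodimer of LKDECFR carrying the spare dehydroalanine:

```bash
$ lalms simulate --seed 7 --out-dir sim
20 species simulated -> sim

$ lalms identify --ms "sim/ms.txt@pH=12,days=6,rep=1" \
                 --msms "sim/msms_016.mgf@pH=12,days=6,rep=1" \
                 --out results.tsv
1 result rows -> results.tsv

$ cat results.tsv
crosslink      annotation                 theoretical_mz observed_mz delta  matched_by_ions required_by_ions confirmed ...
lysinoalanine  LKDE*C*FR - L*K*DE[DHA]FR  1835.929       1835.880    -0.049 24              7                True      ...
```

Reading the row: the precursor matched the theoretical [M+H]⁺ 1835.929
within the 0.2 Da MS tolerance (observed 1835.880, Δ −0.049); 24 distinct
b/y ions matched in MS/MS against the required minimum of 7 (the length of
LKDECFR), so the sequence is confirmed. The annotation marks the bridge
residues with asterisks (Cys donor on one chain, Lys acceptor on the
other) and `[DHA]` the spare dehydroalanine on the non-bridged cysteine.

In Python the same masses come straight from the chemistry core:

```python
>>> from lalms import model_peptides, CrosslinkSpecies, crosslink_mass, mz
>>> llslr, llklf, lkdecfr = model_peptides()
>>> ss = CrosslinkSpecies(lkdecfr, lkdecfr, "disulfide", 4, 4)
>>> round(mz(crosslink_mass(ss)), 2)
1901.89
```

Other subcommands: `lalms build-db` (candidate TSV), `lalms fragment`
(theoretical ions for one species), `lalms trends` (TIC-normalized pH/time
series with direction statistics).

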