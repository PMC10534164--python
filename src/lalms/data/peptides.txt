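# Model peptide definitions (1-based site indices).
# Terminal conventions are those that reproduce the identified crosslink
# masses: LKDECFR is modeled with a free-acid C-terminus and no arginine
# protection in crosslinked species.

[peptide]
name = LLSLR
sequence = LLSLR
n_term = acetyl
c_term = amide
protections = R:5:arg_NO2

[peptide]
name = LLKLF
sequence = LLKLF
n_term = acetyl
c_term = amide

[peptide]
name = LKDECFR
sequence = LKDECFR
n_term = acetyl
c_term = free_acid
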