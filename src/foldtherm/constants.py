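"""Physical constants used package-wide.

Internal unit system: lengths in Å, energies in kcal/mol, times in ns
(folding times in µs where noted), temperatures in K.
"""

#: Gas constant in kcal/mol/K.
R_KCAL = 1.9872e-3
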