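# van der Waals radii in Angstrom.
# Bondi (1964) values; transition metals missing from that set use
# Batsanov (2001) equilibrium radii. Override with VdwRadiusTable.from_file.
H   1.20
B   1.92
C   1.70
N   1.55
O   1.52
F   1.47
Na  2.27
Mg  1.73
Si  2.10
P   1.80
S   1.80
Cl  1.75
K   2.75
Ca  2.31
Mn  2.05
Fe  2.05
Co  2.00
Ni  1.63
Cu  1.40
Zn  1.39
Se  1.90
Br  1.85
Cd  1.58
Te  2.06
I   1.98
At  2.02
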