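# Wimley-White interfacial hydropathy scale (water -> POPC bilayer interface),
# kcal/mol, per-residue transfer free energies. Hydrophobic residues are
# negative under this sign convention. Charged-state values are used for
# D, E, K, R; His is taken as neutral.
# Format: one_letter_code<TAB>delta_G_kcal_per_mol
A	0.17
R	0.81
N	0.42
D	1.23
C	-0.24
Q	0.58
E	2.02
G	0.01
H	0.17
I	-0.31
L	-0.56
K	0.99
M	-0.23
F	-1.13
P	0.45
S	0.13
T	0.14
W	-1.85
Y	-0.94
V	0.07
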