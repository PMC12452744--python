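# Wimley-White octanol hydropathy scale (water -> n-octanol), kcal/mol.
# Alternative sub-scale, selectable via configuration; charged-state values
# for D, E, K, R; His neutral.
# Format: one_letter_code<TAB>delta_G_kcal_per_mol
A	0.50
R	1.81
N	0.85
D	3.64
C	-0.02
Q	0.77
E	3.63
G	1.15
H	0.11
I	-1.12
L	-1.25
K	2.80
M	-0.67
F	-1.71
P	0.14
S	0.46
T	0.25
W	-2.09
Y	-0.71
V	-0.46
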