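# Dipeptide instability weight values (DIWV), Guruprasad et al. 1990.
# Format: first_residue<TAB>second_residue<TAB>weight
# All 400 ordered pairs of the 20 canonical amino acids.
A	A	1
A	C	44.94
A	D	-7.49
A	E	1
A	F	1
A	G	1
A	H	-7.49
A	I	1
A	K	1
A	L	1
A	M	1
A	N	1
A	P	20.26
A	Q	1
A	R	1
A	S	1
A	T	1
A	V	1
A	W	1
A	Y	1
C	A	1
C	C	1
C	D	20.26
C	E	1
C	F	1
C	G	1
C	H	33.6
C	I	1
C	K	1
C	L	20.26
C	M	33.6
C	N	1
C	P	20.26
C	Q	-6.54
C	R	1
C	S	1
C	T	33.6
C	V	-6.54
C	W	24.68
C	Y	1
D	A	1
D	C	1
D	D	1
D	E	1
D	F	-6.54
D	G	1
D	H	1
D	I	1
D	K	-7.49
D	L	1
D	M	1
D	N	1
D	P	1
D	Q	1
D	R	-6.54
D	S	20.26
D	T	-14.03
D	V	1
D	W	1
D	Y	1
E	A	1
E	C	44.94
E	D	20.26
E	E	33.6
E	F	1
E	G	1
E	H	-6.54
E	I	20.26
E	K	1
E	L	1
E	M	1
E	N	1
E	P	20.26
E	Q	20.26
E	R	1
E	S	20.26
E	T	1
E	V	1
E	W	-14.03
E	Y	1
F	A	1
F	C	1
F	D	13.34
F	E	1
F	F	1
F	G	1
F	H	1
F	I	1
F	K	-14.03
F	L	1
F	M	1
F	N	1
F	P	20.26
F	Q	1
F	R	1
F	S	1
F	T	1
F	V	1
F	W	1
F	Y	33.601
G	A	-7.49
G	C	1
G	D	1
G	E	-6.54
G	F	1
G	G	13.34
G	H	1
G	I	-7.49
G	K	-7.49
G	L	1
G	M	1
G	N	-7.49
G	P	1
G	Q	1
G	R	1
G	S	1
G	T	-7.49
G	V	1
G	W	13.34
G	Y	-7.49
H	A	1
H	C	1
H	D	1
H	E	1
H	F	-9.37
H	G	-9.37
H	H	1
H	I	44.94
H	K	24.68
H	L	1
H	M	1
H	N	24.68
H	P	-1.88
H	Q	1
H	R	1
H	S	1
H	T	-6.54
H	V	1
H	W	-1.88
H	Y	44.94
I	A	1
I	C	1
I	D	1
I	E	44.94
I	F	1
I	G	1
I	H	13.34
I	I	1
I	K	-7.49
I	L	20.26
I	M	1
I	N	1
I	P	-1.88
I	Q	1
I	R	1
I	S	1
I	T	1
I	V	-7.49
I	W	1
I	Y	1
K	A	1
K	C	1
K	D	1
K	E	1
K	F	1
K	G	-7.49
K	H	1
K	I	-7.49
K	K	1
K	L	-7.49
K	M	33.6
K	N	1
K	P	-6.54
K	Q	24.64
K	R	33.6
K	S	1
K	T	1
K	V	-7.49
K	W	1
K	Y	1
L	A	1
L	C	1
L	D	1
L	E	1
L	F	1
L	G	1
L	H	1
L	I	1
L	K	-7.49
L	L	1
L	M	1
L	N	1
L	P	20.26
L	Q	33.6
L	R	20.26
L	S	1
L	T	1
L	V	1
L	W	24.68
L	Y	1
M	A	13.34
M	C	1
M	D	1
M	E	1
M	F	1
M	G	1
M	H	58.28
M	I	1
M	K	1
M	L	1
M	M	-1.88
M	N	1
M	P	44.94
M	Q	-6.54
M	R	-6.54
M	S	44.94
M	T	-1.88
M	V	1
M	W	1
M	Y	24.68
N	A	1
N	C	-1.88
N	D	1
N	E	1
N	F	-14.03
N	G	-14.03
N	H	1
N	I	44.94
N	K	24.68
N	L	1
N	M	1
N	N	1
N	P	-1.88
N	Q	-6.54
N	R	1
N	S	1
N	T	-7.49
N	V	1
N	W	-9.37
N	Y	1
P	A	20.26
P	C	-6.54
P	D	-6.54
P	E	18.38
P	F	20.26
P	G	1
P	H	1
P	I	1
P	K	1
P	L	1
P	M	-6.54
P	N	1
P	P	20.26
P	Q	20.26
P	R	-6.54
P	S	20.26
P	T	1
P	V	20.26
P	W	-1.88
P	Y	1
Q	A	1
Q	C	-6.54
Q	D	20.26
Q	E	20.26
Q	F	-6.54
Q	G	1
Q	H	1
Q	I	1
Q	K	1
Q	L	1
Q	M	1
Q	N	1
Q	P	20.26
Q	Q	20.26
Q	R	1
Q	S	44.94
Q	T	1
Q	V	-6.54
Q	W	1
Q	Y	-6.54
R	A	1
R	C	1
R	D	1
R	E	1
R	F	1
R	G	-7.49
R	H	20.26
R	I	1
R	K	1
R	L	1
R	M	1
R	N	13.34
R	P	20.26
R	Q	20.26
R	R	58.28
R	S	44.94
R	T	1
R	V	1
R	W	58.28
R	Y	-6.54
S	A	1
S	C	33.6
S	D	1
S	E	20.26
S	F	1
S	G	1
S	H	1
S	I	1
S	K	1
S	L	1
S	M	1
S	N	1
S	P	44.94
S	Q	20.26
S	R	20.26
S	S	20.26
S	T	1
S	V	1
S	W	1
S	Y	1
T	A	1
T	C	1
T	D	1
T	E	20.26
T	F	13.34
T	G	-7.49
T	H	1
T	I	1
T	K	1
T	L	1
T	M	1
T	N	-14.03
T	P	1
T	Q	-6.54
T	R	1
T	S	1
T	T	1
T	V	1
T	W	-14.03
T	Y	1
V	A	1
V	C	1
V	D	-14.03
V	E	1
V	F	1
V	G	-7.49
V	H	1
V	I	1
V	K	-1.88
V	L	1
V	M	1
V	N	1
V	P	20.26
V	Q	1
V	R	1
V	S	1
V	T	-7.49
V	V	1
V	W	1
V	Y	-6.54
W	A	-14.03
W	C	1
W	D	1
W	E	1
W	F	1
W	G	-9.37
W	H	24.68
W	I	1
W	K	1
W	L	13.34
W	M	24.68
W	N	13.34
W	P	1
W	Q	1
W	R	1
W	S	1
W	T	-14.03
W	V	-7.49
W	W	1
W	Y	1
Y	A	24.68
Y	C	1
Y	D	24.68
Y	E	-6.54
Y	F	1
Y	G	-7.49
Y	H	13.34
Y	I	1
Y	K	1
Y	L	1
Y	M	44.94
Y	N	1
Y	P	13.34
Y	Q	1
Y	R	-15.91
Y	S	1
Y	T	-7.49
Y	V	1
Y	W	-9.37
Y	Y	13.34
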