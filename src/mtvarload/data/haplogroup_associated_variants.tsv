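haplogroup	position	ref	alt	score	frequency
C	8584	G	A	0.553	0.0501
D	8414	C	T	0.513	0.0401
HV	15204	T	C	0.547	0.0125
I	13780	A	G	0.606	0.0176
J	3394	T	C	0.783	0.0136
K	14798	T	C	0.609	0.0676
N	15257	G	A	0.785	0.0161
R	12811	T	C	0.587	0.0108
T	4216	T	C	0.611	0.1001
T	4917	A	G	0.628	0.0475
U	5460	G	A	0.505	0.0623
V	15812	G	A	0.518	0.0102
X	11969	G	A	0.639	0.0134
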