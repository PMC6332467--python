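position	ref	alt	frequency
3394	T	C	0.0136
4216	T	C	0.1001
4917	A	G	0.0475
5460	G	A	0.0623
8414	C	T	0.0401
8584	G	A	0.0501
11969	G	A	0.0134
12811	T	C	0.0108
13780	A	G	0.0176
14798	T	C	0.0676
15204	T	C	0.0125
15257	G	A	0.0161
15812	G	A	0.0102
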