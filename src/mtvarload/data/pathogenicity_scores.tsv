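position	ref	alt	score
3394	T	C	0.783
4216	T	C	0.611
4917	A	G	0.628
5460	G	A	0.505
8414	C	T	0.513
8584	G	A	0.553
11969	G	A	0.639
12811	T	C	0.587
13780	A	G	0.606
14798	T	C	0.609
15204	T	C	0.547
15257	G	A	0.785
15812	G	A	0.518
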