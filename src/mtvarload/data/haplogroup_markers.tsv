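haplogroup	position	alt
C	3552	A
C	9545	G
D	4883	T
D	5178	A
G	709	A
G	4833	G
H	263	G
H	8860	G
H	15326	G
HV	72	C
HV	14766	C
I	1719	A
I	10034	C
I	16129	A
J	295	T
J	489	C
J	4216	C
J	13708	A
K	1189	C
K	10550	G
K	11467	G
K	12308	G
K	12372	A
N	8701	G
N	9540	C
R	5442	C
R	16390	A
T	4216	C
T	4917	G
T	13368	A
T	15607	G
U	11467	G
U	12308	G
U	12372	A
V	4580	A
V	15904	T
W	204	C
W	1243	C
W	11947	G
X	6221	C
X	6371	T
X	14470	C
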