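haplogroup	t2dm	obesity	atherosclerosis	control
C	1	0	1	1
D	0	1	0	2
G	0	0	1	0
H	42	37	40	43
HV	0	1	1	2
I	5	2	3	1
J	9	13	10	7
K	4	6	3	6
N	0	2	2	0
R	1	0	0	2
T	10	14	14	8
U	22	12	15	30
V	1	6	3	8
W	3	3	6	3
X	2	3	1	2
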