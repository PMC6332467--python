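position	ref	alt	label
3243	A	G	MELAS/MIDD
1555	A	G	deafness
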