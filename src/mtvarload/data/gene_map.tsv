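gene	start	end	strand	class
MT-TF	577	647	heavy	tRNA
MT-RNR1	648	1601	heavy	rRNA
MT-TV	1602	1670	heavy	tRNA
MT-RNR2	1671	3229	heavy	rRNA
MT-TL1	3230	3304	heavy	tRNA
MT-ND1	3307	4262	heavy	protein
MT-TI	4263	4331	heavy	tRNA
MT-TQ	4329	4400	light	tRNA
MT-TM	4402	4469	heavy	tRNA
MT-ND2	4470	5511	heavy	protein
MT-TW	5512	5579	heavy	tRNA
MT-TA	5587	5655	light	tRNA
MT-TN	5657	5729	light	tRNA
MT-TC	5761	5826	light	tRNA
MT-TY	5826	5891	light	tRNA
MT-CO1	5904	7445	heavy	protein
MT-TS1	7446	7514	light	tRNA
MT-TD	7518	7585	heavy	tRNA
MT-CO2	7586	8269	heavy	protein
MT-TK	8295	8364	heavy	tRNA
MT-ATP8	8366	8572	heavy	protein
MT-ATP6	8527	9207	heavy	protein
MT-CO3	9207	9990	heavy	protein
MT-TG	9991	10058	heavy	tRNA
MT-ND3	10059	10404	heavy	protein
MT-TR	10405	10469	heavy	tRNA
MT-ND4L	10470	10766	heavy	protein
MT-ND4	10760	12137	heavy	protein
MT-TH	12138	12206	heavy	tRNA
MT-TS2	12207	12265	heavy	tRNA
MT-TL2	12266	12336	heavy	tRNA
MT-ND5	12337	14148	heavy	protein
MT-ND6	14149	14673	light	protein
MT-TE	14674	14742	light	tRNA
MT-CYB	14747	15887	heavy	protein
MT-TT	15888	15953	heavy	tRNA
MT-TP	15956	16023	light	tRNA
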