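name	start	end	strand	ftype	complex	incomplete_stop
tRNA-Phe	577	647	H	tRNA	none	0
12S rRNA	648	1601	H	rRNA	none	0
tRNA-Val	1602	1670	H	tRNA	none	0
16S rRNA	1671	3229	H	rRNA	none	0
tRNA-Leu(UUR)	3230	3304	H	tRNA	none	0
MT-ND1	3307	4262	H	protein	I	2
tRNA-Ile	4263	4331	H	tRNA	none	0
tRNA-Gln	4329	4400	L	tRNA	none	0
tRNA-Met	4402	4469	H	tRNA	none	0
MT-ND2	4470	5511	H	protein	I	1
tRNA-Trp	5512	5579	H	tRNA	none	0
tRNA-Ala	5587	5655	L	tRNA	none	0
tRNA-Asn	5657	5729	L	tRNA	none	0
tRNA-Cys	5761	5826	L	tRNA	none	0
tRNA-Tyr	5826	5891	L	tRNA	none	0
MT-CO1	5904	7445	H	protein	IV	0
tRNA-Ser(UCN)	7446	7514	L	tRNA	none	0
tRNA-Asp	7518	7585	H	tRNA	none	0
MT-CO2	7586	8269	H	protein	IV	0
tRNA-Lys	8295	8364	H	tRNA	none	0
MT-ATP8	8366	8572	H	protein	V	0
MT-ATP6	8527	9207	H	protein	V	0
MT-CO3	9207	9990	H	protein	IV	1
tRNA-Gly	9991	10058	H	tRNA	none	0
MT-ND3	10059	10404	H	protein	I	1
tRNA-Arg	10405	10469	H	tRNA	none	0
MT-ND4L	10470	10766	H	protein	I	0
MT-ND4	10760	12137	H	protein	I	1
tRNA-His	12138	12206	H	tRNA	none	0
tRNA-Ser(AGY)	12207	12265	H	tRNA	none	0
tRNA-Leu(CUN)	12266	12336	H	tRNA	none	0
MT-ND5	12337	14148	H	protein	I	0
MT-ND6	14149	14673	L	protein	I	0
tRNA-Glu	14674	14742	L	tRNA	none	0
MT-CYB	14747	15887	H	protein	III	1
tRNA-Thr	15888	15953	H	tRNA	none	0
tRNA-Pro	15956	16023	L	tRNA	none	0
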