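name	start	end	strand	kind	frame_offset
MT-TF	577	647	+	trna	0
MT-RNR1	648	1601	+	rrna	0
MT-TV	1602	1670	+	trna	0
MT-RNR2	1671	3229	+	rrna	0
MT-TL1	3230	3304	+	trna	0
MT-ND1	3307	4262	+	protein	0
MT-TI	4263	4331	+	trna	0
MT-TQ	4329	4400	-	trna	0
MT-TM	4402	4469	+	trna	0
MT-ND2	4470	5511	+	protein	0
MT-TW	5512	5579	+	trna	0
MT-TA	5587	5655	-	trna	0
MT-TN	5657	5729	-	trna	0
MT-TC	5761	5826	-	trna	0
MT-TY	5826	5891	-	trna	0
MT-CO1	5904	7445	+	protein	0
MT-TS1	7446	7514	-	trna	0
MT-TD	7518	7585	+	trna	0
MT-CO2	7586	8269	+	protein	0
MT-TK	8295	8364	+	trna	0
MT-ATP8	8366	8572	+	protein	0
MT-ATP6	8527	9207	+	protein	0
MT-CO3	9207	9990	+	protein	0
MT-TG	9991	10058	+	trna	0
MT-ND3	10059	10404	+	protein	0
MT-TR	10405	10469	+	trna	0
MT-ND4L	10470	10766	+	protein	0
MT-ND4	10760	12137	+	protein	0
MT-TH	12138	12206	+	trna	0
MT-TS2	12207	12265	+	trna	0
MT-TL2	12266	12336	+	trna	0
MT-ND5	12337	14148	+	protein	0
MT-ND6	14149	14673	-	protein	0
MT-TE	14674	14742	-	trna	0
MT-CYB	14747	15887	+	protein	0
MT-TT	15888	15953	+	trna	0
MT-TP	15956	16023	-	trna	0
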