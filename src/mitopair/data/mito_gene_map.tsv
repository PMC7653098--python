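name	start	end	strand	category	complex
DLOOP	16024	576	H	dloop	.
TRNF	577	647	H	tRNA	.
RNR1	648	1601	H	rRNA	.
TRNV	1602	1670	H	tRNA	.
RNR2	1671	3229	H	rRNA	.
TRNL1	3230	3304	H	tRNA	.
NC1	3305	3306	H	intergenic	.
ND1	3307	4262	H	protein	I
TRNI	4263	4331	H	tRNA	.
TRNQ	4329	4400	L	tRNA	.
NC2	4401	4401	H	intergenic	.
TRNM	4402	4469	H	tRNA	.
ND2	4470	5511	H	protein	I
TRNW	5512	5579	H	tRNA	.
NC3	5580	5586	H	intergenic	.
TRNA	5587	5655	L	tRNA	.
NC4	5656	5656	H	intergenic	.
TRNN	5657	5729	L	tRNA	.
NC11	5730	5760	H	intergenic	.
OLR1	5721	5798	L	regulatory	.
TRNC	5761	5826	L	tRNA	.
TRNY	5826	5891	L	tRNA	.
NC5	5892	5903	H	intergenic	.
CO1	5904	7445	H	protein	IV
TRNS1	7446	7514	L	tRNA	.
NC6	7515	7517	H	intergenic	.
TRND	7518	7585	H	tRNA	.
CO2	7586	8269	H	protein	IV
NC7	8270	8294	H	intergenic	.
TRNK	8295	8364	H	tRNA	.
NC8	8365	8365	H	intergenic	.
ATP8	8366	8572	H	protein	V
ATP6	8527	9207	H	protein	V
CO3	9207	9990	H	protein	IV
TRNG	9991	10058	H	tRNA	.
ND3	10059	10404	H	protein	I
TRNR	10405	10469	H	tRNA	.
ND4L	10470	10766	H	protein	I
ND4	10760	12137	H	protein	I
TRNH	12138	12206	H	tRNA	.
TRNS2	12207	12265	H	tRNA	.
TRNL2	12266	12336	H	tRNA	.
ND5	12337	14148	H	protein	I
ND6	14149	14673	L	protein	I
TRNE	14674	14742	L	tRNA	.
NC10	14743	14746	H	intergenic	.
CYB	14747	15887	H	protein	III
TRNT	15888	15953	H	tRNA	.
NC9	15954	15955	H	intergenic	.
TRNP	15956	16023	L	tRNA	.
LPS	192	445	L	regulatory	.
CSB1	213	235	H	regulatory	.
CSB2	299	315	H	regulatory	.
CSB3	346	363	H	regulatory	.
HSP1	545	567	H	regulatory	.
TAS	16157	16172	H	regulatory	.
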