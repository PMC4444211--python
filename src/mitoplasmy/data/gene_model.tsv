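# Human mitochondrial gene model, snapshot of the NC_012920.1 annotation.
# Coordinates are 1-based inclusive on the heavy strand.
name	start	end	strand	kind
TRNF	577	647	heavy	tRNA
RNR1	648	1601	heavy	rRNA
TRNV	1602	1670	heavy	tRNA
RNR2	1671	3229	heavy	rRNA
TRNL1	3230	3304	heavy	tRNA
ND1	3307	4262	heavy	protein
TRNI	4263	4331	heavy	tRNA
TRNQ	4329	4400	light	tRNA
TRNM	4402	4469	heavy	tRNA
ND2	4470	5511	heavy	protein
TRNW	5512	5579	heavy	tRNA
TRNA	5587	5655	light	tRNA
TRNN	5657	5729	light	tRNA
TRNC	5761	5826	light	tRNA
TRNY	5826	5891	light	tRNA
COX1	5904	7445	heavy	protein
TRNS1	7446	7514	light	tRNA
TRND	7518	7585	heavy	tRNA
COX2	7586	8269	heavy	protein
TRNK	8295	8364	heavy	tRNA
ATP8	8366	8572	heavy	protein
ATP6	8527	9207	heavy	protein
COX3	9207	9990	heavy	protein
TRNG	9991	10058	heavy	tRNA
ND3	10059	10404	heavy	protein
TRNR	10405	10469	heavy	tRNA
ND4L	10470	10766	heavy	protein
ND4	10760	12137	heavy	protein
TRNH	12138	12206	heavy	tRNA
TRNS2	12207	12265	heavy	tRNA
TRNL2	12266	12336	heavy	tRNA
ND5	12337	14148	heavy	protein
ND6	14149	14673	light	protein
TRNE	14674	14742	light	tRNA
CYTB	14747	15887	heavy	protein
TRNT	15888	15953	heavy	tRNA
TRNP	15956	16023	light	tRNA
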