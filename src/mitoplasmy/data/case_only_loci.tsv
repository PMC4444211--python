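# Non-synonymous homoplasmic substitutions observed only in cases (DLPFC),
# with per-diagnosis subject observation counts and catalog counts
# (MitoMap N out of 26,850 GenBank mtDNA sequences).
# self_deposit=1 marks counts attributable to this cohort's own NCBI deposit.
position	gene	bd	mdd	sz	total	ref	alt	aa_change	prediction	mitomap_n	self_deposit
3509	ND1	0	1	0	1	T	C	Ile68Thr	benign	3	1
3796	ND1	0	1	1	2	A	G	Thr164Ala	benign	157	0
3992	ND1	0	0	2	2	C	T	Thr229Met	benign	212	0
4024	ND1	0	0	2	2	A	G	Thr240Ala	benign	166	0
4025	ND1	0	0	1	1	C	T	Thr240Met	benign	254	0
4561	ND2	0	1	0	1	T	C	Val31Ala	benign	221	0
4732	ND2	0	0	1	1	A	G	Asn88Ser	benign	198	0
4824	ND2	1	0	1	2	A	G	Thr119Ala	possibly damaging	746	0
4924	ND2	0	1	0	1	G	C	Ser152Thr	benign	7	1
5073	ND2	0	0	1	1	A	G	Ile202Val	benign	1	0
5277	ND2	0	0	1	1	T	C	Phe270Leu	benign	75	0
5913	COX1	0	0	1	1	G	A	Asp4Asn	benign	191	0
6366	COX1	1	0	0	1	G	A	Val155Ile	benign	98	0
6480	COX1	0	1	0	1	G	A	Val193Ile	benign	70	0
8108	COX2	1	0	0	1	A	G	Ile175Val	benign	45	0
8463	ATP8	1	0	0	1	A	G	Tyr33Cys	probably damaging	8	1
8519	ATP8	0	1	0	1	G	A	Glu52Lys	possibly damaging	63	0
8794	ATP6	1	0	1	2	C	T	His90Tyr	benign	726	0
8843	ATP6	1	0	0	1	T	C	Ile106Thr	possibly damaging	119	0
9055	ATP6	0	2	1	3	G	A	Ala177Thr	possibly damaging	1401	0
9160	ATP6	1	0	0	1	T	C	Tyr212His	probably damaging	1	0
9210	COX3	0	0	1	1	A	G	Thr2Ala	benign	33	0
11016	ND4	1	0	0	1	G	A	Ser86Asn	benign	184	0
11204	ND4	1	0	0	1	T	C	Phe149Leu	benign	100	0
12346	ND5	0	0	1	1	C	T	His4Tyr	unknown	168	0
12397	ND5	1	0	0	1	A	G	Thr21Ala	unknown	134	0
12811	ND5	0	0	1	1	T	C	Tyr159His	benign	214	0
13117	ND5	0	1	0	1	A	G	Ile261Val	possibly damaging	47	0
13637	ND5	0	0	1	1	A	G	Gln434Arg	benign	243	0
13708	ND5	1	0	1	2	G	A	Ala458Thr	benign	1912	0
14110	ND5	0	1	0	1	T	C	Phe592Leu	benign	247	0
14280	ND6	0	0	1	1	A	C	Ser132Ala	benign	2	0
14502	ND6	1	0	0	1	T	C	Ile58Val	benign	111	0
14582	ND6	0	0	2	2	A	G	Val31Ala	benign	164	0
14798	CYTB	1	2	1	4	T	C	Phe18Leu	benign	2114	0
14982	CYTB	0	1	0	1	T	C	Ile79Thr	possibly damaging	2	0
15431	CYTB	1	0	0	1	G	A	Ala229Thr	benign	326	0
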