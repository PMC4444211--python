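# Known-variant frequency catalog fixture (observation counts out of a
# 26,850-genome catalog). self=1 flags counts that stem from this cohort's
# own sequence deposit and can be discounted when classifying novelty.
position	alt	count	catalog_size	self
3509	C	3	26850	1
3796	G	157	26850	0
3992	T	212	26850	0
4024	G	166	26850	0
4025	T	254	26850	0
4561	C	221	26850	0
4732	G	198	26850	0
4824	G	746	26850	0
4924	C	7	26850	1
5073	G	1	26850	0
5277	C	75	26850	0
5913	A	191	26850	0
6366	A	98	26850	0
6480	A	70	26850	0
8108	G	45	26850	0
8463	G	8	26850	1
8519	A	63	26850	0
8642	C	0	26850	0
8794	T	726	26850	0
8843	C	119	26850	0
8945	C	1	26850	0
9055	A	1401	26850	0
9160	C	1	26850	0
9210	G	33	26850	0
11016	A	184	26850	0
11204	C	100	26850	0
12346	T	168	26850	0
12397	G	134	26850	0
12811	C	214	26850	0
13117	G	47	26850	0
13637	G	243	26850	0
13708	A	1912	26850	0
14110	C	247	26850	0
14280	C	2	26850	0
14502	C	111	26850	0
14582	G	164	26850	0
14798	C	2114	26850	0
14982	C	2	26850	0
15431	A	326	26850	0
16178	G	0	26850	0
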