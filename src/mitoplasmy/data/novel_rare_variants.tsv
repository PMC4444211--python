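# Novel and rare non-synonymous mutations (plus one non-coding D-loop variant)
# confirmed by Sanger sequencing in DLPFC samples. Damage-prediction labels are
# opaque pass-through strings (external tool output, not recomputed here).
gene	position	ref	alt	coverage	aa_change	prediction	diagnosis	status
ATP6	8945	T	C	2820	Met140Thr	damaging	Control	Rare
ATP6	8642	A	C	2572	Asn39Thr	damaging	Control	Novel
ATP6	9160	T	C	28247	Tyr212His	damaging	BD	Novel
CYTB	14982	T	C	12465	Ile79Thr	moderate	MDD	Rare
ND6	14280	A	C	1113	Ser132Ala	benign	SZ	Novel
ND2	5073	A	G	20128	Ile202Val	benign	SZ	Novel
D-loop	16178	T	G	22475	-	-	SZ	Novel
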