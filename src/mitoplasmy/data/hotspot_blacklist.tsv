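# Platform error-hotspot blacklist: calls matching these (position, ref, alt)
# entries failed orthogonal validation (Sanger / LNA allele-specific PCR).
# The four A>C entries additionally match the >=2A-then->=2C context motif.
position	ref	alt	reason
302	A	C	motif_AC
3492	A	C	motif_AC
6419	A	C	motif_AC
10306	A	C	motif_AC
3488	T	A	validation_failed
6415	T	A	validation_failed
9801	G	T	validation_failed
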