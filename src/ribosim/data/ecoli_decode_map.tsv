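# E. coli K12 elongator tRNA species and their cognate codons (standard
# wobble-decoding assignments; editable config input, not hard-coded truth).
Ala1B	GCA,GCU,GCG
Ala2	GCC
Arg2	CGU,CGC,CGA
Arg3	CGG
Arg4	AGA
Arg5	AGG
Asn	AAU,AAC
Asp1	GAU,GAC
Cys	UGU,UGC
Gln1	CAA
Gln2	CAG
Glu2	GAA,GAG
Gly1	GGG
Gly2	GGA,GGG
Gly3	GGU,GGC
His	CAU,CAC
Ile1	AUU,AUC
Ile2	AUA
Leu1	CUG
Leu2	CUU,CUC
Leu3	CUA,CUG
Leu4	UUG
Leu5	UUA,UUG
Lys	AAA,AAG
Metm	AUG
Phe	UUU,UUC
Pro1	CCA,CCU
Pro2	CCC
Pro3	CCG
Ser1	UCA,UCU,UCG
Ser2	UCG
Ser3	AGC,AGU
Ser5	UCC,UCU
Thr1	ACC,ACU
Thr2	ACG
Thr3	ACC,ACU
Thr4	ACA,ACU
Trp	UGG
Tyr1	UAU,UAC
Tyr2	UAU,UAC
Val1	GUA,GUG,GUU
Val2	GUC,GUU
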