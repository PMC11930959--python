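id	motif_type	loop_length	triplet	symbol
1	loop	7	AGC	L7:AGC
2	interloop	11	CCG	I11:CCG
3	interloop	5	GCG	I5:GCG
4	interloop	15	CCC	I15:CCC
5	loop	15	UGU	L15:UGU
6	interloop	13	CUG	I13:CUG
7	loop	9	CUU	L9:CUU
8	loop	17	UAA	L17:UAA
9	interloop	9	CUC	I9:CUC
10	loop	13	AUG	L13:AUG
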