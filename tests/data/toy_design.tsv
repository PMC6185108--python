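sample_id	genotype	pair_id
C1	control	1
C2	control	2
C3	control	3
C4	control	4
M1	mutant	1
M2	mutant	2
M3	mutant	3
M4	mutant	4
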