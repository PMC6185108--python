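feature_id	n_control	n_mutant	expected
g01	4	4	testable
g02	3	4	testable
g03	4	0	exclusive_control
g04	3	0	exclusive_control
g05	0	4	exclusive_mutant
g06	0	3	exclusive_mutant
g07	2	4	filtered_out
g08	2	0	filtered_out
g09	0	2	filtered_out
g10	1	1	filtered_out
g11	4	1	testable
g12	4	2	testable
g13	3	3	testable
g14	0	0	filtered_out
g15	4	3	testable
g16	1	4	filtered_out
g17	2	2	filtered_out
g18	3	1	testable
g19	2	3	filtered_out
g20	4	4	testable
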