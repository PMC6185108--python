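feature_id	expected
p01	retained
p02	retained
p03	retained
p04	retained
p05	retained
p06	retained
p07	filtered_out
p08	filtered_out
p09	filtered_out
p10	filtered_out
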