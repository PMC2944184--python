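tip	state
t1	0
t5	0
t4	0
t2	1
t3	1
t8	1
t6	1
t7	1
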