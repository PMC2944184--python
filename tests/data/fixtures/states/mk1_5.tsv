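tip	state
t1	1
t2	1
t3	1
t5	1
t4	1
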