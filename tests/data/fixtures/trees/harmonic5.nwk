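((((L01:0.20000000000000001,L02:0.20000000000000001):0.25,L03:0.45000000000000001):0.33333333333333331,L04:0.78333333333333333):0.49999999999999989,L05:1.2833333333333332);
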