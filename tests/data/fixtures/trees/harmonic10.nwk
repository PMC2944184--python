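(((((((((L01:0.10000000000000001,L02:0.10000000000000001):0.1111111111111111,L03:0.21111111111111111):0.12500000000000003,L04:0.33611111111111114):0.14285714285714285,L05:0.47896825396825399):0.16666666666666669,L06:0.64563492063492067):0.20000000000000007,L07:0.84563492063492074):0.25,L08:1.0956349206349207):0.33333333333333326,L09:1.428968253968254):0.5,L10:1.928968253968254);
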