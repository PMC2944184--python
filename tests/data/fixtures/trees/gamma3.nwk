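((A:1.0,B:1.0):1.0,C:2.0);
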