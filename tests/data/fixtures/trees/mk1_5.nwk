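(t1:0.55465981228170558,(t2:0.41918138876516137,((t3:0.093908547430160083,t5:0.093908547430160083):0.27223753141848034,t4:0.36614607884864042):0.053035309916520945):0.13547842351654421);
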