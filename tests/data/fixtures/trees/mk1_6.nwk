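((t1:0.01097110443064727,t6:0.01097110443064727):0.83248817682199949,(t2:0.6868761493123785,(t3:0.63949366928692664,(t4:0.055112562407699621,t5:0.055112562407699621):0.58438110687922706):0.047382480025451867):0.15658313194026829);
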