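(((t1:0.25277081618635311,t5:0.25277081618635311):0.37204599949498829,t4:0.6248168156813414):0.630104191170197,(t2:0.70491190595265052,((t3:0.12687094794959641,t8:0.12687094794959641):0.11291361731252492,(t6:0.16781026700857266,t7:0.16781026700857266):0.071974298253548674):0.46512734069052919):0.55000910089888788);
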