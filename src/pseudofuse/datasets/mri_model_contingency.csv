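both_correct,baseline_wrong_model_correct,baseline_correct_model_wrong,both_wrong
1265,30,15,1
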