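split,accuracy_pct,n_test
90/10,98.39,1311
40/60,96.87,1311
10/90,90.08,1311
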