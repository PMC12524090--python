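split,supervised_mean,supervised_sd,ssl_mean,ssl_sd
90/10,98.81,0.19,99.08,0.12
50/50,95.19,1.03,96.10,0.92
10/90,84.74,1.42,86.04,1.58
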