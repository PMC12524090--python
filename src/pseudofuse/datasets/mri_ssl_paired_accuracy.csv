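split,supervised_custom_cnn,supervised_resnet50,ssl_custom_cnn,ssl_resnet50
90/10,98.81,99.08,99.08,98.70
80/20,98.09,98.62,98.24,98.62
70/30,97.88,97.63,98.15,98.01
60/40,96.56,97.77,97.17,97.71
50/50,95.19,96.26,96.10,96.26
40/60,94.93,95.19,95.34,97.02
30/70,92.40,94.05,93.21,94.81
20/80,88.90,92.75,90.08,94.43
10/90,84.74,84.50,86.04,86.57
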