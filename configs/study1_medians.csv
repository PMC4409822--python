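0.23,0.27,0.3,0.36,0.44,0.49
0.18,0.21,0.26,0.3,0.39,0.44
0.11,0.14,0.18,0.23,0.3,0.36
0.06,0.09,0.14,0.18,0.26,0.3
0.03,0.05,0.09,0.13,0.21,0.27
0.02,0.03,0.06,0.1,0.18,0.23
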