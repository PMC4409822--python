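0.22,0.26,0.3,0.34
0.16,0.2,0.24,0.28
0.1,0.14,0.18,0.22
0.04,0.08,0.12,0.16
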