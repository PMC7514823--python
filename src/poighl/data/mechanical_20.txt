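0.067
0.068
0.076
0.081
0.084
0.085
0.085
0.086
0.089
0.098
0.098
0.114
0.114
0.115
0.121
0.125
0.131
0.149
0.16
0.485
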