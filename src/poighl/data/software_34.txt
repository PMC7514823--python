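9
12
11
4
7
2
5
8
5
7
1
6
1
9
4
1
3
3
6
1
11
33
7
91
2
1
87
47
12
9
135
258
16
35
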