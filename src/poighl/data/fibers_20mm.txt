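1.312
1.314
1.479
1.552
1.7
1.803
1.861
1.865
1.944
1.958
1.966
1.997
2.006
2.021
2.027
2.055
2.063
2.098
2.14
2.179
2.224
2.24
2.253
2.27
2.272
2.274
2.301
2.301
2.359
2.382
2.382
2.426
2.434
2.435
2.478
2.49
2.511
2.514
2.535
2.554
2.566
2.57
2.586
2.629
2.633
2.642
2.648
2.684
2.697
2.726
2.77
2.773
2.8
2.809
2.818
2.821
2.848
2.88
2.954
3.012
3.067
3.084
3.09
3.096
3.128
3.233
3.433
3.585
3.585
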