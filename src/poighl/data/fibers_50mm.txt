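1.339
1.434
1.549
1.574
1.589
1.613
1.746
1.753
1.764
1.807
1.812
1.84
1.852
1.852
1.862
1.864
1.931
1.952
1.974
2.019
2.051
2.055
2.058
2.088
2.125
2.162
2.171
2.172
2.18
2.194
2.211
2.27
2.272
2.28
2.299
2.308
2.335
2.349
2.356
2.386
2.39
2.41
2.43
2.431
2.458
2.471
2.497
2.514
2.558
2.577
2.593
2.601
2.604
2.62
2.633
2.67
2.682
2.699
2.705
2.735
2.785
3.02
3.042
3.116
3.174
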