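segment,pre_mm,post_mm
1,11.13,11.74
2,8.33,8.33
3,7.62,7.92
4,5.83,7.00
5,5.84,7.38
6,5.86,6.68
7,5.78,7.23
8,5.48,6.54
9,7.63,7.59
10,7.64,7.95
11,11.41,10.59
12,12.84,12.08
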