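segment,pre_mm,post_mm
1,11.82,12.14
2,9.37,9.76
3,7.01,7.72
4,10.00,10.18
5,4.25,4.70
6,7.60,8.56
7,8.15,8.85
8,9.46,9.83
9,10.52,11.27
10,14.40,14.33
11,13.29,13.47
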