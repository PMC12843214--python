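segment,pre_mm,post_mm
1,1.07,1.03
2,0.87,1.03
3,0.45,0.53
4,0.38,1.05
5,0.18,0.42
6,0.31,0.48
7,0.30,0.47
8,0.50,0.75
9,0.77,1.07
10,0.33,0.57
11,0.60,0.70
12,0.25,0.41
13,0.38,0.81
14,0.37,0.61
15,0.80,1.35
16,1.11,1.28
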