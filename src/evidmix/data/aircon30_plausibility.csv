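id,pl_1,pl_2
1,0.9971,0.0080
2,0.9980,0.0057
3,0.9987,0.0038
4,0.9992,0.0022
5,0.9999,0.0003
6,0.9999,0.0003
7,0.9999,0.0003
8,1.0000,0.0001
9,1.0000,0.0001
10,1.0000,0.0001
11,1.0000,0.0001
12,0.9998,0.0006
13,0.9998,0.0006
14,0.9989,0.0035
15,0.9985,0.0047
16,0.9976,0.0076
17,0.9775,0.0858
18,0.9687,0.1264
19,0.9590,0.1770
20,0.9388,0.3094
21,0.9247,0.4584
22,0.9247,0.4584
23,0.9266,0.7394
24,0.9319,0.7860
25,0.9435,0.8549
26,1.0000,1.0000
27,1.0000,1.0000
28,0.0001,1.0000
29,0.0189,0.9930
30,0.0474,0.9813
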