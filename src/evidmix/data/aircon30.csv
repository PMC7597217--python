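time
1
3
5
7
11
11
11
12
14
14
14
16
16
20
21
23
42
47
52
62
71
71
87
90
95
120
120
225
246
261
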