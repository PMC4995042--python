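druse_id,sd_low_octa,sd_low_oct,ss_low_octa,ss_low_oct
1,1,1,0,0
2,1,1,0,0
3,1,1,0,0
4,1,1,0,0
5,1,1,0,0
6,1,1,0,0
7,1,1,0,0
8,1,1,0,0
9,1,1,0,0
10,1,1,0,0
11,1,1,1,0
12,1,1,1,0
13,1,1,1,0
14,1,1,1,0
15,1,0,1,0
16,1,0,1,0
17,1,0,1,0
18,0,0,0,0
19,0,0,0,0
20,0,0,0,0
21,0,0,0,0
22,0,0,0,0
23,0,0,0,0
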