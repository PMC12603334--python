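# Photodiode angular sensitivity vs exit polar angle in air.
# Default: cosine response (unit at normal incidence).
angle_deg,sensitivity
0,1.000000
5,0.996195
10,0.984808
15,0.965926
20,0.939693
25,0.906308
30,0.866025
35,0.819152
40,0.766044
45,0.707107
50,0.642788
55,0.573576
60,0.500000
65,0.422618
70,0.342020
75,0.258819
80,0.173648
85,0.087156
90,0.000000
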