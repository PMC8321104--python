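triplet_id,correct_label,votefor_A,votefor_C,agreement_23,agreement_34,t_correctness_ratio
1,C,0.21,0.79,1,1,0.79
2,C,0.97,0.03,1,1,0.03
3,C,0.72,0.28,1,0,0.28
4,A,0.00,1.00,1,1,0.00
5,A,0.03,0.97,1,1,0.03
6,A,0.97,0.03,1,1,0.97
7,A,0.72,0.28,1,0,0.72
8,C,0.93,0.07,1,1,0.07
9,C,1.00,0.00,1,1,0.00
10,C,0.90,0.10,1,1,0.10
11,A,1.00,0.00,1,1,1.00
12,C,0.72,0.28,1,0,0.28
13,C,0.07,0.93,1,1,0.93
14,C,0.72,0.28,1,0,0.28
15,A,0.34,0.66,1,0,0.34
16,C,0.07,0.93,1,1,0.93
17,A,0.66,0.34,1,0,0.66
18,A,0.55,0.45,0,0,0.55
19,A,0.07,0.93,1,1,0.07
20,C,0.07,0.93,1,1,0.93
21,C,0.03,0.97,1,1,0.97
22,C,0.00,1.00,1,1,1.00
23,A,0.76,0.24,1,1,0.76
24,A,0.97,0.03,1,1,0.97
25,C,0.55,0.45,0,0,0.45
26,A,0.14,0.86,1,1,0.14
27,A,0.00,1.00,1,1,0.00
28,A,0.00,1.00,1,1,0.00
29,C,0.14,0.86,1,1,0.86
30,A,0.97,0.03,1,1,0.97
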