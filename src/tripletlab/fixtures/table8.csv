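triplet_id,annotator_stated_u,asba_uncertainty,annotator_correctness,asba_correctness
1,0.30,0.91,0.79,0.00
2,0.26,0.93,0.03,0.00
3,0.63,0.93,0.28,0.00
4,0.21,0.44,0.00,1.00
5,0.38,0.60,0.03,1.00
6,0.41,0.79,0.97,1.00
7,0.64,0.94,0.72,1.00
8,0.26,0.70,0.07,0.00
9,0.15,0.35,0.00,1.00
10,0.55,0.69,0.10,0.00
11,0.09,0.19,1.00,1.00
12,0.57,0.89,0.28,0.00
13,0.34,0.43,0.93,1.00
14,0.67,0.63,0.28,0.00
15,0.60,0.87,0.34,1.00
16,0.23,0.59,0.93,1.00
17,0.58,0.97,0.66,1.00
18,0.76,0.90,0.55,1.00
19,0.38,0.33,0.07,1.00
20,0.48,0.58,0.93,1.00
21,0.22,0.43,0.97,1.00
22,0.36,0.45,1.00,1.00
23,0.71,0.92,0.76,0.00
24,0.46,0.47,0.97,1.00
25,0.62,0.82,0.45,1.00
26,0.57,0.96,0.14,0.00
27,0.39,0.64,0.00,0.00
28,0.40,0.74,0.00,0.00
29,0.39,0.58,0.86,0.00
30,0.29,0.77,0.97,1.00
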