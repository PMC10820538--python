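rank,antecedent,consequent,n,support,confidence,lift,is
1,N08,N18,3523,0.051,0.457,5.239,0.519
2,N18,N08,3523,0.051,0.589,5.239,0.519
3,E11;N18,N08,2683,0.039,0.677,6.017,0.485
4,I10,E11,12259,0.179,0.632,1.217,0.467
5,E11,I10,12259,0.179,0.344,1.217,0.467
6,E11;N08,N18,2683,0.039,0.462,5.294,0.455
7,I10;N08,N18,1811,0.026,0.525,6.018,0.399
8,I10;N18,N08,1811,0.026,0.626,5.561,0.383
9,E11;I10;N08,N18,1429,0.021,0.537,6.159,0.358
10,E11;I10;N18,N08,1429,0.021,0.689,6.128,0.358
11,E11,N08,5808,0.085,0.163,1.451,0.351
12,N08,E11,5808,0.085,0.754,1.451,0.351
13,H36,E11,5256,0.077,0.757,1.457,0.334
14,E11,H36,5256,0.077,0.148,1.457,0.334
15,G63,E11,3973,0.058,0.791,1.522,0.297
16,E11,G63,3973,0.058,0.112,1.522,0.297
17,E78,E11,4406,0.064,0.683,1.314,0.291
18,E11,E78,4406,0.064,0.124,1.314,0.291
19,N08,I10,3449,0.05,0.448,1.581,0.282
20,I10,N08,3449,0.05,0.178,1.581,0.282
21,E11;I10,N08,2659,0.039,0.217,1.928,0.274
22,N18,E11,3964,0.058,0.663,1.277,0.272
23,E11,N18,3964,0.058,0.111,1.277,0.272
24,E78,I10,3008,0.044,0.466,1.647,0.269
25,I10,E78,3008,0.044,0.155,1.647,0.269
26,I10,N18,2895,0.042,0.149,1.711,0.269
27,N18,I10,2895,0.042,0.484,1.711,0.269
28,E14,I10,4079,0.06,0.309,1.093,0.255
29,I10,E14,4079,0.06,0.21,1.093,0.255
30,E11;N08,I10,2659,0.039,0.458,1.617,0.251
31,E11;I10,E78,2226,0.032,0.182,1.928,0.25
32,H36,N08,1778,0.026,0.256,2.275,0.243
33,N08,H36,1778,0.026,0.231,2.275,0.243
34,E11;I10,N18,2073,0.03,0.169,1.938,0.242
35,E11;E78,I10,2226,0.032,0.505,1.785,0.241
36,I10;N08,E11,2659,0.039,0.771,1.484,0.24
37,N08;N18,E11,2683,0.039,0.762,1.466,0.24
38,E11;N18,I10,2073,0.03,0.523,1.847,0.236
39,E11;N08,H36,1467,0.021,0.253,2.491,0.231
40,E11;H36,N08,1467,0.021,0.279,2.481,0.23
41,N08;N18,I10,1811,0.026,0.514,1.816,0.219
42,E78;I10,E11,2226,0.032,0.74,1.425,0.215
43,E87,I10,2614,0.038,0.333,1.178,0.212
44,I10,E87,2614,0.038,0.135,1.178,0.212
45,I10;N18,E11,2073,0.03,0.716,1.379,0.204
46,H36;I10,E11,1789,0.026,0.825,1.589,0.204
47,E11;N08;N18,I10,1429,0.021,0.533,1.882,0.198
48,E11;I10,H36,1789,0.026,0.146,1.439,0.194
49,E11;I10,G63,1483,0.022,0.121,1.65,0.189
50,H36,I10,2168,0.032,0.312,1.102,0.187
51,I10,H36,2168,0.032,0.112,1.102,0.187
52,G63;I10,E11,1483,0.022,0.829,1.596,0.186
53,H36;N08,E11,1467,0.021,0.825,1.588,0.184
54,G63,I10,1789,0.026,0.356,1.258,0.181
55,I10;N08;N18,E11,1429,0.021,0.789,1.519,0.178
56,K29,E11,2052,0.03,0.549,1.056,0.178
57,E11;H36,I10,1789,0.026,0.34,1.202,0.177
58,E11;G63,I10,1483,0.022,0.373,1.319,0.169
59,N08,E14,1560,0.023,0.202,1.052,0.155
60,E14,N08,1560,0.023,0.118,1.052,0.155
61,K21,E11,1533,0.022,0.553,1.064,0.154
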