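id,r1,r2,r3,r4,r5,exp_pec50,comfa_pred,comfa_res,comsia_pred,comsia_res,role
1,dimethyl-mino,phenyl,H,Cl,OH,7.208,7.188,0.020,7.129,0.079,train
2,methyl,phenyl,H,Cl,OH,6.005,6.260,-0.255,6.280,-0.275,test
3,ethyl,phenyl,H,Cl,OH,6.730,6.884,-0.154,6.921,-0.191,train
4,n-propyl,phenyl,H,Cl,OH,7.174,7.149,0.025,7.107,0.067,train
5,n-butyl,phenyl,H,Cl,OH,6.951,7.097,-0.146,7.143,-0.192,train
6,isopropyl,phenyl,H,Cl,OH,7.328,7.078,0.250,7.267,0.061,test
7,sec-butyl,phenyl,H,Cl,OH,6.992,6.900,0.092,6.951,0.041,train
8,tert-butyl,phenyl,H,Cl,OH,6.833,6.887,-0.054,6.939,-0.106,train
9,cyclopropyl,phenyl,H,Cl,OH,6.987,6.921,0.066,6.998,-0.011,train
10,cyclobutyl,phenyl,H,Cl,OH,6.695,6.558,0.137,6.601,0.094,train
11,cyclopentyl,phenyl,H,Cl,OH,6.460,6.548,-0.088,6.564,-0.104,train
12,cyclohexyl,phenyl,H,Cl,OH,6.234,6.265,-0.031,6.260,-0.026,test
13,isopropyl,isopropyl,H,Cl,OH,7.237,6.865,0.372,6.890,0.347,test
14,isopropyl,n-hexyl,H,Cl,OH,6.550,6.555,-0.005,6.495,0.010,train
15,isopropyl,cyclohexyl,H,Cl,OH,8.000,7.624,0.376,7.610,0.390,test
16,isopropyl,ethoxycarbonylethyl,H,Cl,OH,6.320,6.405,-0.085,6.346,-0.026,test
17,isopropyl,allyl,H,Cl,OH,7.259,7.185,0.074,7.177,0.082,test
18,isopropyl,2-methylphenyl,H,Cl,OH,7.468,7.232,0.236,7.089,0.379,train
19,isopropyl,3-methylphenyl,H,Cl,OH,6.959,6.947,0.012,6.997,-0.038,train
20,isopropyl,4-methylphenyl,H,Cl,OH,7.108,7.021,0.087,7.025,0.083,train
21,isopropyl,"2,6-dimethylphenyl",H,Cl,OH,6.813,6.929,-0.116,6.987,-0.174,train
22,isopropyl,"2,3-dimethylphenyl",H,Cl,OH,7.143,7.321,-0.178,7.163,-0.020,train
23,isopropyl,"2,4-dimethylphenyl",H,Cl,OH,6.747,7.394,-0.647,7.202,-0.455,test
24,isopropyl,2-ethylphenyl,H,Cl,OH,6.907,7.045,-0.138,7.226,-0.319,train
25,isopropyl,2-chlorophenyl,H,Cl,OH,7.268,7.178,0.090,7.218,0.050,train
26,isopropyl,3-chlorophenyl,H,Cl,OH,7.456,7.377,0.079,7.376,0.080,train
27,isopropyl,3-chloro-2-methylphenyl,H,Cl,OH,7.509,7.399,0.110,7.472,0.037,train
28,isopropyl,3-chloro-4-methylphenyl,H,Cl,OH,7.328,7.448,-0.120,7.481,-0.153,train
29,isopropyl,2-methoxylphenyl,H,Cl,OH,6.975,6.933,0.042,7.019,-0.044,train
30,isopropyl,3-methoxylphenyl,H,Cl,OH,6.587,7.015,-0.428,6.839,-0.252,test
31,isopropyl,4-methoxylphenyl,H,Cl,OH,6.600,6.574,0.026,6.707,-0.107,train
32,isopropyl,"2,4-dimethoxyphenyl",H,Cl,OH,6.058,6.182,-0.124,6.321,-0.263,test
33,isopropyl,3-pyridyl,H,Cl,OH,6.449,6.613,-0.164,6.623,-0.174,test
34,isopropyl,benzyl,H,Cl,OH,6.201,6.268,-0.067,6.195,0.006,train
35,isopropyl,phenethyl,H,Cl,OH,6.034,6.077,-0.043,6.013,0.021,train
36,isopropyl,4-phenylbutyl,H,Cl,OH,5.741,5.952,-0.211,6.053,-0.312,test
37,isopropyl,phenyl,H,H,H,5.908,5.726,0.182,5.753,0.155,train
38,isopropyl,phenyl,H,H,OH,6.914,6.653,0.261,6.794,0.120,test
39,isopropyl,phenyl,H,F,OH,6.648,6.719,-0.071,6.726,-0.078,train
40,isopropyl,phenyl,H,CH3,OH,7.432,7.674,-0.242,6.928,-0.496,test
41,isopropyl,phenyl,H,OCH3,OH,6.699,6.654,0.045,6.597,0.102,train
42,isopropyl,phenyl,H,H,OCH3,6.697,6.696,0.001,6.731,-0.034,train
43,isopropyl,phenyl,H,OCH3,OCH3,6.650,6.739,-0.089,6.695,-0.045,train
44,isopropyl,phenyl,H,H,NH(CH3)2,6.830,6.914,-0.084,6.669,0.161,train
45,isopropyl,phenyl,H,H,Br,5.984,6.112,-0.128,5.829,0.155,train
46,isopropyl,phenyl,H,OCH3,H,6.733,6.521,0.212,6.299,0.434,test
47,isopropyl,phenyl,H,OH,H,6.124,6.008,0.116,6.087,0.037,test
48,isopropyl,phenyl,H,OH,OCH3,6.353,6.283,0.070,6.471,-0.118,train
49,isopropyl,phenyl,CH3,H,H,5.190,5.196,-0.006,5.609,-0.419,train
50,isopropyl,phenyl,H,H,CH2OH,6.389,6.433,-0.044,6.233,0.156,train
51,isopropyl,phenyl,H,H,(CH2)2OH,6.991,6.572,0.419,6.431,0.560,test
52,isopropyl,phenyl,H,H,(CH2)3OH,7.009,6.848,0.162,6.975,0.034,test
53,isopropyl,phenyl,H,H,O(CH2)2OH,7.022,7.031,-0.009,6.905,0.117,train
54,isopropyl,phenyl,H,H,O(CH2)3OH,7.237,6.979,0.258,6.859,0.378,test
55,isopropyl,phenyl,H,H,OCH(CH2OH)2,5.064,5.607,-0.543,5.438,-0.374,test
56,isopropyl,phenyl,H,O(CH2)2OH,H,5.850,5.762,0.088,5.815,0.035,train
57,isopropyl,phenyl,H,H,O(CH2)3N(CH3)2,6.465,6.512,-0.047,6.535,-0.070,train
58,n-propyl,2-methylphenyl,H,Cl,OH,7.721,7.538,0.183,7.279,0.442,train
59,n-propyl,2-methylphenyl,H,Cl,O(CH2)2OH,7.959,7.933,0.026,8.154,-0.195,train
60,isopropyl,2-methylphenyl,H,Cl,(R)-OCH2CH(CH3)CH2OH,8.041,8.026,0.015,8.031,0.010,train
61,isopropyl,2-methylphenyl,H,Cl,(S)-OCH2CH(CH3)CH2OH,8.013,8.061,-0.048,7.907,0.106,train
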