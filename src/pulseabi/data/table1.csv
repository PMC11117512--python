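id,sex,age,weight_kg,height_m,trad_r,trad_l,sys_r,sys_l,censored
1,F,77,76,1.535,1.03,1.12,1.083,1.137,0
2,F,61,59,1.53,1.18,1.20,1.132,1.104,0
3,F,46,93,1.64,1.10,1.13,1.018,1.118,0
4,F,56,93.5,1.63,1.35,1.23,1.071,1.099,0
5,F,52,46.5,1.465,1.14,1.14,1.079,1.014,0
6,F,66,75.3,1.48,1.11,1.11,1.107,1.021,0
7,F,74,60.5,1.55,1.21,1.26,1.199,1.166,0
8,F,79,75.2,1.49,1.17,1.05,1.081,1.245,0
9,F,64,70,1.535,1.18,1.12,0.960,1.204,0
10,M,54,87,1.64,1.02,1.01,0.932,0.974,0
11,M,73,71,1.63,1.30,1.30,1.309,1.348,1
12,M,47,83.1,1.875,1.19,1.19,0.931,0.909,0
13,M,49,79,1.79,1.18,1.20,1.066,1.005,0
14,M,86,72,1.65,1.20,1.32,1.110,1.099,0
15,M,75,96.5,1.64,1.08,1.23,0.918,1.000,0
16,M,67,57.8,1.78,1.26,1.21,1.348,1.326,0
17,M,64,108.7,1.71,1.07,1.14,1.134,1.061,0
18,M,48,66,1.73,1.09,1.15,1.063,1.207,0
19,M,55,79.3,1.68,1.16,1.26,1.079,1.112,0
20,M,66,91,1.695,1.00,0.89,1.078,0.896,0
21,M,83,93.5,1.61,1.30,1.30,1.064,1.136,0
22,M,73,53.5,1.66,1.21,1.27,1.155,1.246,0
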