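sample,patient_id,cancer_status,pack_years,sex,age,smoking_status,histology,brock_score,tp53_prevalence,protocol_id,risk_score_x100
1,7047,NC,25,M,57,Former,NC,0.86,0.000,0398,
2,7768,NC,20,F,52,Current,NC,1.07,0.005,0398,
3,8115,NC,36,M,56,Former,NC,0.66,0.000,1078,
4,9277,NC,20,F,60,Former,NC,0.94,0.000,1078,
5,9680,NC,31,F,63,Former,NC,0.97,0.010,1078,
6,12028,NC,14.5,F,50,Current,NC,0.4,0.015,0398,
7,12318,NC,6,M,71,Former,NC,0.68,0.005,0398,
8,7871,NC,45,M,69,Former,NC,9.31,0.020,0398,
9,8027,NC,78,F,55,Current,NC,5.88,0.026,1078,
10,8182,NC,110,M,61,Former,NC,11.07,0.005,1078,
11,8202,NC,78,M,66,Current,NC,7.05,0.010,1078,
12,8356,NC,42,F,72,Former,NC,6.15,0.005,1078,
13,9299,NC,75,M,64,Current,NC,5.26,0.000,1078,
14,11858,NC,20,M,74,Former,NC,6.59,0.000,0398,
15,7878,NC,30,F,58,Current,NC,2.15,0.005,1078,
16,7319,NC,0,M,28,Never,NC,0.04,0.005,0398,
17,7282,NC,0,F,33,Never,NC,0.08,0.000,0398,
18,7291,NC,0,M,38,Never,NC,0.1,0.010,0398,
19,10660,NC,0,F,41,Never,NC,0.14,0.000,0398,
20,9425,NC,66,F,70,Current,NC,7.16,0.015,1078,
21,9022,NC,51,M,60,Former,NC,4.16,0.020,1078,
22,8978,NC,51,M,65,Current,NC,8.48,0.000,1078,
23,12444,NC,60,F,68,Current,NC,11.28,Not measured,1078,
24,6359,CA,44,M,68,Former,SQ,8.55,0.041,0398,
25,11143,CA,47,M,65,Current,AD,16.79,0.005,0398,
26,11761,CA,78,M,49,Current,AD,5.25,0.026,0398,
27,11841,CA,72,M,51,Current,AD,2.19,0.026,0398,
28,11704,CA,72,F,61,Current,SQ,14.6,0.031,0398,
29,7481,CA,150,M,78,Former,SQ,14.95,0.005,0398,
30,8841,CA,185.5,M,76,Former,SQ,22.88,0.041,0398,
31,7725,CA,60,M,79,Current,SQ,25.61,0.041,0398,
32,8358,CA,50,M,60,Current,SQ,9.42,0.056,0398,
33,8439,CA,92,M,62,Former,SQ,5.3,0.051,0398,
34,7801,CA,25,F,65,Current,SQ,2.65,0.036,0398,
35,7509,CA,100,M,68,Current,SQ,13.74,0.026,0398,
36,7492,CA,40,M,63,Current,SQ,4.29,0.020,0398,
37,8340,CA,108,M,64,Former,SQ,9.93,0.031,0398,
38,11583,NC,39,M,63,Former,NC,1.38,0.005,0398,
39,9420,NC,62.5,F,59,Former,NC,2.1,0.000,1078,
40,7769,NC,0,M,70,Never,NC,1.65,0.000,0398,
41,11202,NC,0,F,52,Never,NC,0.55,0.000,0398,
42,11917,NC,0,F,81,Never,NC,6.93,0.000,0398,
43,15667,NC,0,M,57,Never,NC,1.18,0.005,0398,
44,7979,NC,62,F,61,Former,NC,1.73,0.000,1078,
45,12847,CA,15,F,59,Former,AD,2.28,0.000,0398,
46,3857,CA,47,F,67,Former,AD,7.17,0.010,0398,
47,3955,CA,88,F,58,Current,AD,14,0.031,0398,
48,6077,CA,88,F,58,Current,AD,14.37,0.010,0398,
49,7757,CA,45,M,74,Former,AD,11.15,0.097,0398,
50,7781,CA,99.9,F,60,Former,AD,4.95,0.031,0398,
51,7789,CA,30,F,77,Former,AD,12.04,0.005,0398,
52,7862,CA,74,M,68,Former,AD,4.42,0.010,0398,
53,9517,CA,40,F,61,Former,AD,3.09,0.000,0398,
54,9641,CA,50,F,64,Current,AD,7.31,0.031,0398,
55,9707,CA,60,F,77,Former,AD,11.22,0.005,0398,
56,9798,CA,47,F,69,Current,AD,8.52,0.056,0398,
57,11246,CA,96,F,65,Current,AD,7.35,0.010,0398,
58,12911,CA,15,M,72,Former,AD,5.3,0.046,0398,
59,14611,CA,60,F,69,Current,AD,10.43,0.005,0398,
60,14813,CA,61.5,M,59,Former,AD,6.24,0.031,0398,
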