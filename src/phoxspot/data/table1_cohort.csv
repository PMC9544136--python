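case_id,entity_group,overall_percent,hotspot_percent
1,ETMR,0.6481,4.18
2,ETMR,0.0374,
3,ETMR,0.0473,
4,ETMR,3.265,38.53
5,ETMR,0.461,3.734
6,ETMR,0.7755,16.4
7,ETMR,4.939,39.01
8,PLAGL2-NEC,0.085,0.5272
9,glioma,0.0235,
10,other-CNS-embryonal,0.015,
11,other-CNS-embryonal,0.0066,
12,other-CNS-embryonal,0.0227,
13,other-CNS-embryonal,0.0373,
14,other-CNS-embryonal,0.0314,
15,glioma,0.0098,
16,glioma,0.0122,
17,glioma,0.0331,
18,ATRT,0.0027,
19,ATRT,0.0048,
20,ATRT,0.019,
21,ATRT,0.0298,
22,ATRT,0.004,
23,medulloblastoma,0.003,
24,medulloblastoma,0.009,
25,medulloblastoma,0.0099,
26,medulloblastoma,0.0292,
27,medulloblastoma,0.0304,
28,medulloblastoma,0.0136,
29,neuroblastoma-primary,45.9,90.58
30,neuroblastoma-primary,10.41,94.51
31,neuroblastoma-primary,1.819,38.48
32,neuroblastoma-primary,77.43,99.11
33,neuroblastoma-primary,31.9,12.51
34,neuroblastoma-primary,2.455,96.51
35,neuroblastoma-primary,68.95,97.08
36,neuroblastoma-primary,9.429,55.77
37,neuroblastoma-metastatic,66.06,99.22
38,neuroblastoma-metastatic,33.65,89.67
39,neuroblastoma-metastatic,7.335,85.41
40,neuroblastoma-metastatic,79.22,88.57
41,neuroblastoma-metastatic,46.51,90.67
42,neuroblastoma-metastatic,1.947,7.56
43,neuroblastoma-metastatic,29.38,97.2
44,neuroblastoma-metastatic,63.6,97.15
45,pineoblastoma,0.0073,
46,pineoblastoma,0.0353,
47,pineoblastoma,0.0376,
48,pineoblastoma,0.028,
49,pineoblastoma,0.035,
50,pineoblastoma,0.0104,
51,pineoblastoma,0.0148,
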