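age,sex,noncvd_hazard,cvd_hazard
18,male,0.000361949,0.000680859
19,male,0.000396036,0.000730227
20,male,0.000433332,0.000783175
21,male,0.000474141,0.000839961
22,male,0.000518793,0.000900865
23,male,0.00056765,0.000966185
24,male,0.000621108,0.00103624
25,male,0.0006796,0.00111138
26,male,0.000743601,0.00119196
27,male,0.000813629,0.00127839
28,male,0.000890252,0.00137108
29,male,0.000974091,0.0014705
30,male,0.00106582,0.00157712
31,male,0.0011662,0.00169147
32,male,0.00127602,0.00181412
33,male,0.00139619,0.00194566
34,male,0.00152768,0.00208673
35,male,0.00167155,0.00223804
36,male,0.00182896,0.00240032
37,male,0.0020012,0.00257436
38,male,0.00218967,0.00276102
39,male,0.00239588,0.00296122
40,male,0.00262151,0.00317593
41,male,0.00286838,0.00340621
42,male,0.00313851,0.00365319
43,male,0.00343408,0.00391807
44,male,0.00375748,0.00420217
45,male,0.00411134,0.00450686
46,male,0.00449852,0.00483364
47,male,0.00492217,0.00518412
48,male,0.00538571,0.00556001
49,male,0.00589291,0.00596316
50,male,0.00644787,0.00639554
51,male,0.00705509,0.00685927
52,male,0.0077195,0.00735662
53,male,0.00844647,0.00789003
54,male,0.00924192,0.00846213
55,male,0.0101123,0.0090757
56,male,0.0110646,0.00973376
57,male,0.0121066,0.0104395
58,male,0.0132467,0.0111965
59,male,0.0144942,0.0120083
60,male,0.0158592,0.012879
61,male,0.0173527,0.0138129
62,male,0.0189869,0.0148144
63,male,0.020775,0.0158886
64,male,0.0227314,0.0170406
65,male,0.0248722,0.0182762
66,male,0.0272145,0.0196014
67,male,0.0297774,0.0210227
68,male,0.0325816,0.022547
69,male,0.03565,0.0241818
70,male,0.0390073,0.0259352
71,male,0.0426808,0.0278157
72,male,0.0467002,0.0298326
73,male,0.0510982,0.0319957
74,male,0.0559103,0.0343156
75,male,0.0611756,0.0368038
76,male,0.0669368,0.0394724
77,male,0.0732405,0.0423344
78,male,0.0801379,0.045404
79,male,0.0876849,0.0486962
80,male,0.0959425,0.052227
81,male,0.104978,0.0560139
82,male,0.114864,0.0600754
83,male,0.125681,0.0644314
84,male,0.137517,0.0691032
85,male,0.150468,0.0741137
86,male,0.164638,0.0794876
87,male,0.180143,0.0852511
88,male,0.197107,0.0914324
89,male,0.21567,0.0980621
90,male,0.23598,0.105172
91,male,0.258204,0.112798
92,male,0.28252,0.120977
93,male,0.309126,0.129749
94,male,0.338238,0.139157
95,male,0.370091,0.149247
96,male,0.404944,0.160068
97,male,0.443079,0.171675
98,male,0.484806,0.184122
99,male,0.530462,0.197473
100,male,0.580418,0.211791
18,female,0.00027697,0.000521005
19,female,0.000303053,0.000558783
20,female,0.000331593,0.000599299
21,female,0.000362821,0.000642753
22,female,0.000396989,0.000689358
23,female,0.000434375,0.000739342
24,female,0.000475282,0.00079295
25,female,0.000520042,0.000850446
26,female,0.000569016,0.00091211
27,female,0.000622603,0.000978245
28,female,0.000681236,0.00104918
29,female,0.000745391,0.00112525
30,female,0.000815588,0.00120684
31,female,0.000892395,0.00129435
32,female,0.000976436,0.0013882
33,female,0.00106839,0.00148885
34,female,0.00116901,0.00159681
35,female,0.0012791,0.00171259
36,female,0.00139955,0.00183676
37,female,0.00153136,0.00196994
38,female,0.00167557,0.00211278
39,female,0.00183337,0.00226598
40,female,0.00200602,0.00243028
41,female,0.00219494,0.00260649
42,female,0.00240164,0.00279548
43,female,0.00262782,0.00299818
44,female,0.00287529,0.00321557
45,female,0.00314607,0.00344873
46,female,0.00344235,0.00369879
47,female,0.00376653,0.00396698
48,female,0.00412124,0.00425462
49,female,0.00450935,0.00456311
50,female,0.00493402,0.00489398
51,female,0.00539868,0.00524883
52,female,0.00590709,0.00562941
53,female,0.00646339,0.00603759
54,female,0.00707207,0.00647537
55,female,0.00773808,0.00694488
56,female,0.00846681,0.00744844
57,female,0.00926417,0.00798852
58,female,0.0101366,0.00856775
59,female,0.0110912,0.00918898
60,female,0.0121357,0.00985526
61,female,0.0132786,0.0105698
62,female,0.0145291,0.0113362
63,female,0.0158974,0.0121582
64,female,0.0173945,0.0130398
65,female,0.0190326,0.0139853
66,female,0.020825,0.0149993
67,female,0.0227862,0.0160869
68,female,0.024932,0.0172533
69,female,0.02728,0.0185043
70,female,0.0298491,0.0198461
71,female,0.0326601,0.0212851
72,female,0.0357358,0.0228284
73,female,0.0391012,0.0244836
74,female,0.0427836,0.0262589
75,female,0.0468127,0.0281629
76,female,0.0512212,0.0302049
77,female,0.0560449,0.032395
78,female,0.0613229,0.0347439
79,female,0.067098,0.0372632
80,female,0.0734169,0.039965
81,female,0.0803309,0.0428628
82,female,0.087896,0.0459707
83,female,0.0961735,0.049304
84,female,0.105231,0.0528789
85,female,0.115141,0.0567131
86,female,0.125984,0.0608253
87,female,0.137848,0.0652356
88,female,0.15083,0.0699657
89,female,0.165034,0.0750388
90,female,0.180576,0.0804797
91,female,0.197582,0.0863152
92,female,0.216189,0.0925737
93,female,0.236549,0.0992861
94,female,0.258825,0.106485
95,female,0.2832,0.114206
96,female,0.30987,0.122487
97,female,0.339052,0.131368
98,female,0.370982,0.140894
99,female,0.405919,0.15111
100,female,0.444146,0.162066
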