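compound_id,pIC50,set_label,pred_comfa,pred_comsia
1,5.699,train,5.344,5.391
2,4.699,test,5.063,4.954
3,4.886,train,5.013,4.978
4,5.602,train,5.569,4.973
5,4.921,train,4.773,5.374
6,4.276,test,4.735,5.375
7,4.456,train,4.380,5.364
8,4.444,test,4.401,4.736
9,4.658,train,4.507,4.405
10,4.041,train,4.213,4.249
11,5.495,train,5.595,4.816
12,4.495,train,4.687,5.440
13,5.398,train,5.261,5.001
14,5.824,test,5.799,5.203
15,5.638,train,5.614,5.837
16,6.328,test,6.051,5.811
17,5.569,train,5.714,5.436
18,5.432,test,5.348,5.263
19,5.721,train,5.444,4.948
20,5.585,train,5.516,5.337
21,4.863,train,4.968,4.868
22,5.509,train,5.357,5.261
23,5.004,train,5.168,5.527
24,5.161,test,4.859,5.153
25,5.569,train,5.582,5.290
26,5.161,test,4.910,5.010
27,4.971,train,4.949,4.958
28,5.155,train,5.405,5.060
29,4.762,train,4.809,4.889
30,5.284,train,5.515,5.908
31,5.699,train,5.795,5.811
32,6.337,train,6.322,6.218
33,5.444,train,5.488,5.342
34,5.959,train,5.778,5.473
35,5.585,train,5.599,5.619
36,5.699,train,5.720,5.524
37,5.602,train,5.711,5.511
38,5.032,test,5.160,5.348
39,4.947,train,5.088,5.375
40,4.839,test,5.507,5.107
41,5.602,train,5.457,5.365
42,5.367,test,5.787,5.345
43,4.569,train,4.564,5.374
44,6.027,train,5.884,5.920
45,6.509,train,6.147,5.997
46,6.638,train,6.765,6.124
47,6.824,train,6.841,6.114
48,6.721,test,6.299,6.025
49,5.824,train,5.772,5.824
50,5.770,test,5.765,6.309
51,6.155,train,6.234,6.451
52,6.678,train,6.530,6.624
53,6.137,train,6.221,6.165
54,5.000,train,5.067,5.592
55,5.538,train,5.684,5.918
56,4.876,train,4.854,5.679
57,5.638,train,5.541,5.719
58,5.824,test,5.612,5.715
59,5.420,train,5.518,5.487
60,6.237,test,5.748,5.971
61,4.824,train,4.639,4.696
62,4.569,train,4.696,4.842
63,4.824,test,5.106,4.972
64,4.854,test,5.437,5.382
65,6.854,train,6.827,6.824
66,7.347,train,7.409,7.020
67,6.987,test,6.996,6.470
68,7.699,train,7.577,7.681
69,7.523,train,7.539,7.795
70,7.824,train,7.960,7.422
71,7.081,train,7.100,6.889
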