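age,sex,qx
50,male,0.00310889
51,male,0.00336421
52,male,0.00364773
53,male,0.00396254
54,male,0.00431208
55,male,0.00470018
56,male,0.00513107
57,male,0.00560945
58,male,0.00614051
59,male,0.00673004
60,male,0.00738443
61,male,0.00811076
62,male,0.00891687
63,male,0.00981147
64,male,0.01080416
65,male,0.01190559
66,male,0.01312751
67,male,0.01448295
68,male,0.01598626
69,male,0.01765332
70,male,0.01950163
71,male,0.0215505
72,male,0.02382117
73,male,0.02633706
74,male,0.02912388
75,male,0.03220988
76,male,0.03562604
77,male,0.03940628
78,male,0.04358765
79,male,0.04821062
80,male,0.05331921
81,male,0.05896124
82,male,0.0651885
83,male,0.07205688
84,male,0.07962654
85,male,0.08796187
86,male,0.09713156
87,male,0.1072084
88,male,0.11826907
89,male,0.13039373
90,male,0.14366538
91,male,0.15816905
92,male,0.17399066
93,male,0.19121558
94,male,0.20992676
95,male,0.23020249
96,male,0.25211359
97,male,0.2757202
98,male,0.3010679
99,male,0.32818336
100,male,0.35706947
101,male,0.38770003
102,male,0.42001417
103,male,0.45391073
104,male,0.48924291
105,male,0.52581359
106,male,0.56337188
107,male,0.60161158
108,male,0.64017206
109,male,0.67864257
110,male,1.0
50,female,0.00166794
51,female,0.00181927
52,female,0.00198733
53,female,0.00217397
54,female,0.00238122
55,female,0.00261138
56,female,0.00286695
57,female,0.00315073
58,female,0.00346585
59,female,0.00381573
60,female,0.0042042
61,female,0.0046355
62,female,0.00511433
63,female,0.00564591
64,female,0.006236
65,female,0.00689102
66,female,0.00761804
67,female,0.00842493
68,female,0.00932038
69,female,0.01031402
70,female,0.01141649
71,female,0.01263959
72,female,0.01399632
73,female,0.01550107
74,female,0.01716971
75,female,0.01901978
76,female,0.02107059
77,female,0.02334343
78,female,0.0258617
79,female,0.02865116
80,female,0.03174008
81,female,0.03515947
82,female,0.03894327
83,female,0.04312858
84,female,0.04775589
85,female,0.05286926
86,female,0.05851656
87,female,0.06474961
88,female,0.07162437
89,female,0.07920102
90,female,0.08754403
91,female,0.09672211
92,female,0.10680813
93,female,0.11787882
94,female,0.13001438
95,female,0.14329787
96,female,0.15781438
97,female,0.17364987
98,female,0.19088974
99,female,0.20961696
100,female,0.22990984
101,female,0.2518392
102,female,0.27546516
103,female,0.30083323
104,female,0.32797002
105,female,0.3568783
106,female,0.38753172
107,female,0.4198692
108,female,0.45378935
109,female,0.4891451
110,female,1.0
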