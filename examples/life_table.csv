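# population: synthetic_generic_elderly
# open_ended: false
age,mortality_prob
50,0.00324332
51,0.00356597
52,0.00392065
53,0.00431053
54,0.0047391
55,0.00521016
56,0.00572791
57,0.00629694
58,0.00692231
59,0.00760955
60,0.00836473
61,0.00919451
62,0.01010618
63,0.01110773
64,0.01220793
65,0.01341636
66,0.01474352
67,0.01620088
68,0.01780099
69,0.01955756
70,0.02148556
71,0.02360132
72,0.02592266
73,0.02846897
74,0.03126136
75,0.03432278
76,0.03767812
77,0.04135439
78,0.04538082
79,0.04978901
80,0.05461301
81,0.0598895
82,0.06565784
83,0.0719602
84,0.07884158
85,0.08634986
86,0.09453577
87,0.10345283
88,0.11315722
89,0.12370751
90,0.13516439
91,0.1475902
92,0.16104834
93,0.17560253
94,0.19131586
95,0.20824963
96,0.22646191
97,0.24600596
98,0.26692815
99,0.28926582
100,0.31304465
101,0.33827584
102,0.364953
103,0.39304887
104,0.42251185
105,0.45326267
106,0.48519109
107,0.51815314
108,0.55196895
109,0.58642157
110,1
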