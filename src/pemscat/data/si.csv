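# SI photon interaction coefficients, Z=14, A=28.0855
# energy_keV,pe_cm2_per_g,incoherent_cm2_per_g
10,12.4327,0.192263
10.6457,10.3048,0.191808
11.3331,8.54115,0.191326
12.0649,7.07933,0.190816
12.844,5.8677,0.190278
13.6733,4.86344,0.189709
14.5562,4.03106,0.189108
15.4961,3.34114,0.188475
16.4968,2.7693,0.187806
17.562,2.29533,0.187101
18.696,1.90249,0.186358
19.9032,1.57687,0.185576
21.1884,1.30699,0.184753
22.5565,1.0833,0.183887
24.013,0.897891,0.182978
25.5636,0.744216,0.182023
27.2143,0.616843,0.18102
28.9715,0.51127,0.179969
30.8423,0.423766,0.178869
32.8338,0.351238,0.177716
34.9539,0.291123,0.176512
37.211,0.241298,0.175253
39.6137,0.199999,0.17394
42.1716,0.165769,0.172571
44.8947,0.137398,0.171146
47.7936,0.113882,0.169664
50.8797,0.0943911,0.168124
54.1651,0.078236,0.166526
57.6626,0.0648458,0.164871
61.386,0.0537474,0.163158
65.3498,0.0445485,0.161388
69.5695,0.036924,0.159561
74.0617,0.0306044,0.157679
78.844,0.0253665,0.155742
83.935,0.021025,0.153753
89.3548,0.0174265,0.151712
95.1246,0.014444,0.149622
101.267,0.0119923,0.147485
107.806,0.0100324,0.145303
114.767,0.00840377,0.14308
122.178,0.00704869,0.140817
130.067,0.00591982,0.138519
138.466,0.00497822,0.136188
147.406,0.00419185,0.133829
156.925,0.0035343,0.131443
167.058,0.00298379,0.129036
177.845,0.00252231,0.12661
189.328,0.00213498,0.12417
201.554,0.00180949,0.121719
214.568,0.00153562,0.11926
228.423,0.0013049,0.116797
243.173,0.00111029,0.114334
258.875,0.000945936,0.111873
275.591,0.000806962,0.109418
293.386,0.000689304,0.106971
312.33,0.000589568,0.104536
332.498,0.000504921,0.102115
353.968,0.000432991,0.0997097
376.824,0.000371792,0.0973226
401.156,0.000319659,0.0949555
427.059,0.000275195,0.09261
454.635,0.000237225,0.0902877
483.991,0.00020476,0.0879899
515.243,0.000176969,0.0857176
548.513,0.000153149,0.083472
583.932,0.000132708,0.0812537
621.637,0.000115145,0.0790637
661.777,0.000100037,0.0769024
704.509,8.70245e-05,0.0747706
750,7.58034e-05,0.0726687
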