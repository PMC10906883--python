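# O photon interaction coefficients, Z=8, A=15.999
# energy_keV,pe_cm2_per_g,incoherent_cm2_per_g
10,1.66642,0.192862
10.6457,1.38121,0.192405
11.3331,1.14482,0.191922
12.0649,0.948881,0.191411
12.844,0.78648,0.190871
13.6733,0.651873,0.1903
14.5562,0.540305,0.189698
15.4961,0.447831,0.189062
16.4968,0.371185,0.188391
17.562,0.307656,0.187684
18.696,0.255001,0.186939
19.9032,0.211357,0.186154
21.1884,0.175183,0.185329
22.5565,0.1452,0.18446
24.013,0.120349,0.183548
25.5636,0.0997514,0.18259
27.2143,0.0826789,0.181584
28.9715,0.0685283,0.18053
30.8423,0.0567997,0.179426
32.8338,0.0470784,0.17827
34.9539,0.0390209,0.177062
37.211,0.0323424,0.1758
39.6137,0.026807,0.174482
42.1716,0.022219,0.173109
44.8947,0.0184162,0.171679
47.7936,0.0152642,0.170193
50.8797,0.0126518,0.168648
54.1651,0.0104864,0.167045
57.6626,0.00869164,0.165385
61.386,0.00720406,0.163666
65.3498,0.00597108,0.161891
69.5695,0.00494913,0.160058
74.0617,0.00410208,0.15817
78.844,0.00340001,0.156228
83.935,0.00281809,0.154232
89.3548,0.00233577,0.152185
95.1246,0.00193601,0.150088
101.267,0.0016074,0.147944
107.806,0.0013447,0.145756
114.767,0.0011264,0.143525
122.178,0.000944774,0.141256
130.067,0.000793466,0.138951
138.466,0.000667258,0.136613
147.406,0.000561857,0.134246
156.925,0.000473722,0.131853
167.058,0.000399933,0.129438
177.845,0.000338078,0.127005
189.328,0.000286163,0.124557
201.554,0.000242535,0.122098
214.568,0.000205827,0.119631
228.423,0.000174903,0.117161
243.173,0.000148818,0.11469
258.875,0.000126789,0.112221
275.591,0.000108162,0.109759
293.386,9.23912e-05,0.107305
312.33,7.90231e-05,0.104862
332.498,6.76773e-05,0.102433
353.968,5.80362e-05,0.10002
376.824,4.98333e-05,0.0976259
401.156,4.28457e-05,0.0952514
427.059,3.68859e-05,0.0928986
454.635,3.17965e-05,0.0905691
483.991,2.74451e-05,0.0882641
515.243,2.37201e-05,0.0859848
548.513,2.05274e-05,0.0837321
583.932,1.77876e-05,0.0815069
621.637,1.54335e-05,0.07931
661.777,1.34085e-05,0.0771421
704.509,1.16644e-05,0.0750036
750,1.01603e-05,0.0728952
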