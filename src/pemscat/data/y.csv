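# Y photon interaction coefficients, Z=39, A=88.90584
# energy_keV,pe_cm2_per_g,incoherent_cm2_per_g
10,62.577,0.169194
10.6457,51.8669,0.168793
11.3331,42.9898,0.168369
12.0649,35.6321,0.167921
12.844,29.5336,0.167447
13.6733,24.4789,0.166946
14.5562,20.2894,0.166418
15.4961,16.8168,0.16586
16.4968,13.9386,0.165271
17.038,12.652,0.164955
17.038,88.5637,0.164955
17.562,80.871,0.164651
18.696,67.0299,0.163997
19.9032,55.5577,0.163309
21.1884,46.049,0.162585
22.5565,38.1677,0.161823
24.013,31.6352,0.161023
25.5636,26.2208,0.160182
27.2143,21.7331,0.1593
28.9715,18.0135,0.158375
30.8423,14.9305,0.157406
32.8338,12.3751,0.156393
34.9539,10.2571,0.155332
37.211,8.50159,0.154225
39.6137,7.04654,0.153069
42.1716,5.84052,0.151865
44.8947,4.84091,0.150611
47.7936,4.01239,0.149306
50.8797,3.32566,0.147951
54.1651,2.75647,0.146545
57.6626,2.2847,0.145088
61.386,1.89367,0.143581
65.3498,1.56957,0.142023
69.5695,1.30094,0.140416
74.0617,1.07828,0.138759
78.844,0.893732,0.137055
83.935,0.740769,0.135304
89.3548,0.613986,0.133508
95.1246,0.508902,0.131669
101.267,0.422524,0.129788
107.806,0.353471,0.127868
114.767,0.296089,0.125912
122.178,0.248345,0.123921
130.067,0.208572,0.121898
138.466,0.175397,0.119847
147.406,0.147691,0.117771
156.925,0.124524,0.115672
167.058,0.105127,0.113553
177.845,0.0888679,0.111418
189.328,0.0752213,0.109271
201.554,0.0637533,0.107114
214.568,0.0541041,0.10495
228.423,0.0459752,0.102783
243.173,0.0391186,0.100615
258.875,0.033328,0.0984494
275.591,0.0284315,0.0962889
293.386,0.0242861,0.0941361
312.33,0.0207722,0.0919931
332.498,0.0177898,0.0898623
353.968,0.0152555,0.0877457
376.824,0.0130993,0.085645
401.156,0.0112625,0.0835619
427.059,0.0096959,0.0814979
454.635,0.0083581,0.0794543
483.991,0.00721427,0.0774321
515.243,0.00623511,0.0754325
548.513,0.00539586,0.0734563
583.932,0.00467567,0.0715042
621.637,0.00405689,0.0695769
661.777,0.00352459,0.067675
704.509,0.00306612,0.065799
750,0.00267077,0.0639493
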