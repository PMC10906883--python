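# LU photon interaction coefficients, Z=71, A=174.9668
# energy_keV,pe_cm2_per_g,incoherent_cm2_per_g
10,673.137,0.156514
10.6457,557.929,0.156143
11.3331,462.439,0.155751
12.0649,383.293,0.155336
12.844,317.692,0.154898
13.6733,263.319,0.154435
14.5562,218.251,0.153946
15.4961,180.898,0.15343
16.4968,149.937,0.152885
17.562,124.275,0.152312
18.696,103.005,0.151707
19.9032,85.3759,0.15107
21.1884,70.7637,0.1504
22.5565,58.6525,0.149696
24.013,48.6141,0.148955
25.5636,40.2937,0.148177
27.2143,33.3974,0.147361
28.9715,27.6814,0.146506
30.8423,22.9437,0.14561
32.8338,19.0169,0.144672
34.9539,15.7622,0.143691
37.211,13.0645,0.142667
39.6137,10.8285,0.141598
42.1716,8.97516,0.140484
44.8947,7.43906,0.139323
47.7936,6.16586,0.138117
50.8797,5.11057,0.136863
54.1651,4.23589,0.135563
57.6626,3.51092,0.134215
61.386,2.91002,0.132821
63.3139,2.6522,0.132114
63.3141,13.7913,0.132114
65.3498,12.5422,0.131379
69.5695,10.3956,0.129892
74.0617,8.6164,0.12836
78.844,7.1417,0.126784
83.935,5.91939,0.125164
89.3548,4.90629,0.123503
95.1246,4.06657,0.121801
101.267,3.37634,0.120062
107.806,2.82454,0.118286
114.767,2.36601,0.116476
122.178,1.98449,0.114634
130.067,1.66667,0.112763
138.466,1.40157,0.110866
147.406,1.18018,0.108945
156.925,0.995052,0.107003
167.058,0.840058,0.105043
177.845,0.710132,0.103068
189.328,0.601084,0.101082
201.554,0.509444,0.0990863
214.568,0.432339,0.0970846
228.423,0.367382,0.0950798
243.173,0.312592,0.0930745
258.875,0.26632,0.0910713
275.591,0.227193,0.0890727
293.386,0.194067,0.0870812
312.33,0.165988,0.0850989
332.498,0.142156,0.0831278
353.968,0.121905,0.0811697
376.824,0.104675,0.0792265
401.156,0.0899973,0.0772995
427.059,0.0774787,0.0753902
454.635,0.0667885,0.0734997
483.991,0.0576484,0.0716291
515.243,0.049824,0.0697794
548.513,0.0431177,0.0679513
583.932,0.0373627,0.0661455
621.637,0.0324181,0.0643626
661.777,0.0281645,0.0626033
704.509,0.024501,0.0608678
750,0.0213418,0.0591568
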