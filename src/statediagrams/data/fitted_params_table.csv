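experiment,tgs,k,r2_gt,e,b,r2_chen,tg_prime,tm_prime,ws_prime
1,10.4,2.90,0.986,0.0954,0.1668,0.991,-55.9,-42.8,0.739
2,31.8,3.79,0.994,0.1103,0.0557,0.968,-55.7,-41.8,0.783
3,65.2,4.68,0.975,0.0584,0.0980,0.964,-43.1,-32.5,0.796
4,157.3,10.32,0.808,0.0085,0.1595,0.929,-9.5,-9.5,0.801
5,25.6,3.33,0.990,0.0781,0.2178,0.991,-56.4,-38.7,0.716
6,60.3,5.59,0.983,0.0371,0.1280,0.971,-46.6,-29.6,0.807
7,61.6,5.75,0.964,0.0535,0.0741,0.974,-54.8,-30.2,0.812
8,107,4.09,0.970,0.0256,0.2442,0.975,-44.6,-22.3,0.741
9,24.7,3.53,0.981,0.0877,0.0697,0.950,-50.2,-38.4,0.791
10,41,3.85,0.984,0.0786,0.1076,0.971,-52.0,-38.8,0.781
11,19.1,3.52,0.976,0.0956,0.0936,0.972,-54.6,-42.6,0.781
12,64,6.12,0.876,0.0517,0.1399,0.969,-52.0,-32.0,0.780
13,16.4,3.73,0.954,0.0734,0.1958,0.987,-56.9,-39.3,0.738
14,34.4,4.04,0.987,0.0806,0.1805,0.987,-57.1,-39.0,0.737
15,46.6,4.16,0.951,0.0673,0.1340,0.974,-50.4,-34.7,0.768
16,37.7,4.18,0.899,0.0706,0.1770,0.983,-55.9,-36.9,0.746
17,66,5.44,0.904,0.0552,0.1953,0.966,-51.6,-34.8,0.750
18,73.5,6.41,0.890,0.0553,0.2107,0.988,-52.3,-34.4,0.740
19,47.6,5.06,0.884,0.0385,0.0770,0.967,-47.4,-25.5,0.824
20,52.4,4.43,0.963,0.0529,0.2970,0.986,-55.5,-36.1,0.702
21,67.1,6.09,0.886,0.0700,0.1644,0.985,-55.4,-36.5,0.752
22,92.4,6.90,0.971,0.0408,0.2569,0.981,-48.9,-31.6,0.730
23,18.8,3.75,0.949,0.0841,0.1467,0.985,-56.4,-38.6,0.751
24,36.6,3.43,0.976,0.0583,0.2462,0.984,-53.5,-35.1,0.719
25,54.2,4.78,0.965,0.0801,0.0865,0.977,-55.8,-35.3,0.780
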