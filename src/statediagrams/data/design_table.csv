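experiment,run_order,xf,xg,xs,xp,xa,xm
1,15,1,0,0,0,0,0
2,6,0,1,0,0,0,0
3,8,0,0,1,0,0,0
4,4,0,0,0,0.15,0.05,0.80
5,1,0.283,0.283,0.283,0.075,0.075,0
6,7,0.45,0,0,0.15,0,0.40
7,21,0,0.45,0,0.15,0,0.40
8,2,0,0,0.45,0.15,0,0.40
9,23,0.50,0,0.50,0,0,0
10,22,0,0.50,0.50,0,0,0
11,18,0.50,0.50,0,0,0,0
12,24,0.145,0.145,0.145,0.059,0.15,0.355
13,20,0.70,0,0,0.15,0.15,0
14,5,0,0.70,0,0.15,0.15,0
15,11,0,0,0.70,0.15,0.15,0
16,25,0.327,0.327,0.077,0.035,0.035,0.198
17,19,0.327,0.077,0.327,0.035,0.035,0.198
18,12,0.077,0.327,0.327,0.035,0.035,0.198
19,3,0.177,0.077,0.077,0.035,0.035,0.598
20,9,0.502,0.077,0.077,0.035,0.110,0.198
21,13,0.077,0.540,0.077,0.035,0.073,0.198
22,14,0.077,0.077,0.577,0.035,0.035,0.198
23,10,0.35,0.35,0,0.15,0.15,0
24,17,0.35,0,0.35,0.15,0.15,0
25,16,0,0.35,0.35,0.15,0.15,0
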