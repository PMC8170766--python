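# Utility weight for each integer IPSS score (1-35).
# Strictly decreasing; moderate symptoms span IPSS 7-19.
ipss,utility
1,1
2,0.995
3,0.99
4,0.985
5,0.98
6,0.975
7,0.97
8,0.944
9,0.936
10,0.928
11,0.92
12,0.912
13,0.904
14,0.896
15,0.888
16,0.88
17,0.872
18,0.864
19,0.856
20,0.848
21,0.84
22,0.832
23,0.824
24,0.816
25,0.808
26,0.8
27,0.792
28,0.784
29,0.776
30,0.768
31,0.76
32,0.752
33,0.744
34,0.736
35,0.728
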