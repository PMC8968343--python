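point_index,cluster_id
0,1
1,2
2,4
3,7
4,9
5,1
6,2
7,3
8,4
9,6
10,7
11,8
12,9
13,1
14,10
15,2
16,9
17,3
18,8
19,3
20,8
21,4
22,7
23,5
24,6
25,1
26,10
27,5
28,6
29,1
30,1
31,10
32,2
33,9
34,2
35,9
36,3
37,8
38,4
39,7
40,4
41,7
42,5
43,6
44,6
45,1
46,6
47,1
48,5
49,10
50,6
51,1
52,5
53,10
54,6
55,2
56,4
57,9
58,7
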