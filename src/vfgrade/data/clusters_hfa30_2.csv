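point_index,cluster_id
0,4
1,3
2,3
3,2
4,4
5,4
6,3
7,3
8,2
9,2
10,5
11,4
12,4
13,3
14,3
15,2
16,2
17,1
18,5
19,5
20,5
21,4
22,4
23,2
24,2
25,1
26,1
27,1
28,5
29,5
30,5
31,5
32,4
33,2
34,1
35,1
36,1
37,1
38,6
39,6
40,6
41,6
42,7
43,9
44,10
45,10
46,10
47,10
48,6
49,6
50,6
51,7
52,7
53,9
54,9
55,10
56,10
57,10
58,6
59,7
60,7
61,8
62,8
63,9
64,9
65,10
66,7
67,7
68,8
69,8
70,9
71,9
72,7
73,8
74,8
75,9
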