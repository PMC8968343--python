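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
11,5
12,4
13,4
14,2
15,2
16,1
17,1
18,5
19,5
20,5
21,5
22,4
23,2
24,1
25,1
26,1
27,6
28,6
29,6
30,6
31,7
32,9
33,10
34,10
35,10
36,6
37,6
38,7
39,7
40,9
41,9
42,10
43,10
44,7
45,7
46,8
47,8
48,9
49,9
50,7
51,8
52,8
53,9
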