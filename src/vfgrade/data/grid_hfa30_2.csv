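index,x_deg,y_deg,is_blind_spot
0,-9,27,0
1,-3,27,0
2,3,27,0
3,9,27,0
4,-15,21,0
5,-9,21,0
6,-3,21,0
7,3,21,0
8,9,21,0
9,15,21,0
10,-21,15,0
11,-15,15,0
12,-9,15,0
13,-3,15,0
14,3,15,0
15,9,15,0
16,15,15,0
17,21,15,0
18,-27,9,0
19,-21,9,0
20,-15,9,0
21,-9,9,0
22,-3,9,0
23,3,9,0
24,9,9,0
25,15,9,0
26,21,9,0
27,27,9,0
28,-27,3,0
29,-21,3,0
30,-15,3,0
31,-9,3,0
32,-3,3,0
33,3,3,0
34,9,3,0
35,15,3,1
36,21,3,0
37,27,3,0
38,-27,-3,0
39,-21,-3,0
40,-15,-3,0
41,-9,-3,0
42,-3,-3,0
43,3,-3,0
44,9,-3,0
45,15,-3,1
46,21,-3,0
47,27,-3,0
48,-27,-9,0
49,-21,-9,0
50,-15,-9,0
51,-9,-9,0
52,-3,-9,0
53,3,-9,0
54,9,-9,0
55,15,-9,0
56,21,-9,0
57,27,-9,0
58,-21,-15,0
59,-15,-15,0
60,-9,-15,0
61,-3,-15,0
62,3,-15,0
63,9,-15,0
64,15,-15,0
65,21,-15,0
66,-15,-21,0
67,-9,-21,0
68,-3,-21,0
69,3,-21,0
70,9,-21,0
71,15,-21,0
72,-9,-27,0
73,-3,-27,0
74,3,-27,0
75,9,-27,0
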