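index,x_deg,y_deg,is_blind_spot
0,-9,21,0
1,-3,21,0
2,3,21,0
3,9,21,0
4,-15,15,0
5,-9,15,0
6,-3,15,0
7,3,15,0
8,9,15,0
9,15,15,0
10,-21,9,0
11,-15,9,0
12,-9,9,0
13,-3,9,0
14,3,9,0
15,9,9,0
16,15,9,0
17,21,9,0
18,-27,3,0
19,-21,3,0
20,-15,3,0
21,-9,3,0
22,-3,3,0
23,3,3,0
24,9,3,0
25,15,3,1
26,21,3,0
27,-27,-3,0
28,-21,-3,0
29,-15,-3,0
30,-9,-3,0
31,-3,-3,0
32,3,-3,0
33,9,-3,0
34,15,-3,1
35,21,-3,0
36,-21,-9,0
37,-15,-9,0
38,-9,-9,0
39,-3,-9,0
40,3,-9,0
41,9,-9,0
42,15,-9,0
43,21,-9,0
44,-15,-15,0
45,-9,-15,0
46,-3,-15,0
47,3,-15,0
48,9,-15,0
49,15,-15,0
50,-9,-21,0
51,-3,-21,0
52,3,-21,0
53,9,-21,0
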