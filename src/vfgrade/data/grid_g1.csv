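index,x_deg,y_deg,is_blind_spot
0,0,0,0
1,3,3,0
2,-3,3,0
3,-3,-3,0
4,3,-3,0
5,8,0,0
6,6,6,0
7,0,8,0
8,-6,6,0
9,-8,0,0
10,-6,-6,0
11,0,-8,0
12,6,-6,0
13,12,5,0
14,12,-5,0
15,8,10,0
16,8,-10,0
17,3,13,0
18,3,-13,0
19,-3,13,0
20,-3,-13,0
21,-8,10,0
22,-8,-10,0
23,-12,5,0
24,-12,-5,0
25,15,3,1
26,15,-3,1
27,-15,3,0
28,-15,-3,0
29,20,0,0
30,19,8,0
31,19,-8,0
32,14,14,0
33,14,-14,0
34,7,18,0
35,7,-18,0
36,0,20,0
37,0,-20,0
38,-7,18,0
39,-7,-18,0
40,-14,14,0
41,-14,-14,0
42,-19,8,0
43,-19,-8,0
44,-20,0,0
45,26,0,0
46,-26,0,0
47,24,4,0
48,-24,4,0
49,24,-4,0
50,-24,-4,0
51,23,10,0
52,-23,10,0
53,23,-10,0
54,-23,-10,0
55,16,22,0
56,-16,22,0
57,16,-22,0
58,-16,-22,0
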