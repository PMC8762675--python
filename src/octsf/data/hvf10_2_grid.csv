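locus_id,x_deg,y_deg,ring
0,-1.0,9.0,5
1,1.0,9.0,5
2,-5.0,7.0,5
3,-3.0,7.0,4
4,-1.0,7.0,4
5,1.0,7.0,4
6,3.0,7.0,4
7,5.0,7.0,5
8,-7.0,5.0,5
9,-5.0,5.0,4
10,-3.0,5.0,3
11,-1.0,5.0,3
12,1.0,5.0,3
13,3.0,5.0,3
14,5.0,5.0,4
15,7.0,5.0,5
16,-7.0,3.0,4
17,-5.0,3.0,3
18,-3.0,3.0,2
19,-1.0,3.0,2
20,1.0,3.0,2
21,3.0,3.0,2
22,5.0,3.0,3
23,7.0,3.0,4
24,-9.0,1.0,5
25,-7.0,1.0,4
26,-5.0,1.0,3
27,-3.0,1.0,2
28,-1.0,1.0,1
29,1.0,1.0,1
30,3.0,1.0,2
31,5.0,1.0,3
32,7.0,1.0,4
33,9.0,1.0,5
34,-9.0,-1.0,5
35,-7.0,-1.0,4
36,-5.0,-1.0,3
37,-3.0,-1.0,2
38,-1.0,-1.0,1
39,1.0,-1.0,1
40,3.0,-1.0,2
41,5.0,-1.0,3
42,7.0,-1.0,4
43,9.0,-1.0,5
44,-7.0,-3.0,4
45,-5.0,-3.0,3
46,-3.0,-3.0,2
47,-1.0,-3.0,2
48,1.0,-3.0,2
49,3.0,-3.0,2
50,5.0,-3.0,3
51,7.0,-3.0,4
52,-7.0,-5.0,5
53,-5.0,-5.0,4
54,-3.0,-5.0,3
55,-1.0,-5.0,3
56,1.0,-5.0,3
57,3.0,-5.0,3
58,5.0,-5.0,4
59,7.0,-5.0,5
60,-5.0,-7.0,5
61,-3.0,-7.0,4
62,-1.0,-7.0,4
63,1.0,-7.0,4
64,3.0,-7.0,4
65,5.0,-7.0,5
66,-1.0,-9.0,5
67,1.0,-9.0,5
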