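code,kno3_mg_l,nh4no3_mg_l,cano3_2_4h2o_mg_l,cacl2_2h2o_mg_l
1,1900,1650,556,0
2,1900,1650,280,0
3,1900,1238,556,0
4,1900,1238,280,0
5,1900,825,556,0
6,1900,825,280,0
7,1425,1650,556,0
8,1425,1650,280,0
9,1425,1238,556,0
10,1425,1238,280,0
11,1425,825,556,0
12,1425,825,280,0
13,950,1650,556,0
14,950,1650,280,0
15,950,1238,556,0
16,950,1238,280,0
17,950,825,556,0
18,950,825,280,0
19,1900,1650,0,440
20,1900,1650,0,220
21,1900,1238,0,440
22,1900,1238,0,220
23,1900,825,0,440
24,1900,825,0,220
25,1425,1650,0,440
26,1425,1650,0,220
27,1425,1238,0,440
28,1425,1238,0,220
29,1425,825,0,440
30,1425,825,0,220
31,950,1650,0,440
32,950,1650,0,220
33,950,1238,0,440
34,950,1238,0,220
35,950,825,0,440
36,950,825,0,220
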