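age,qx
0,0.00054
1,0.0005439863542
2,0.0005483699839
3,0.0005531904811
4,0.0005584913836
5,0.0005643205679
6,0.0005707306821
7,0.0005777796209
8,0.0005855310488
9,0.0005940549752
10,0.0006034283864
11,0.0006137359409
12,0.0006250707346
13,0.0006375351408
14,0.0006512417355
15,0.0006663143137
16,0.0006828890078
17,0.0007011155169
18,0.0007211584591
19,0.0007431988579
20,0.0007674357777
21,0.0007940881211
22,0.0008233966066
23,0.0008556259421
24,0.0008910672164
25,0.0009300405274
26,0.0009728978741
27,0.001020026335
28,0.001071851564
29,0.001128841636
30,0.001191511274
31,0.001260426495
32,0.001336209729
33,0.001419545434
34,0.001511186279
35,0.001611959946
36,0.001722776601
37,0.001844637117
38,0.001978642113
39,0.002126001893
40,0.00228804738
41,0.002466242135
42,0.002662195575
43,0.00287767751
44,0.003114634129
45,0.003375205572
46,0.003661745268
47,0.003976841182
48,0.004323339193
49,0.0047043688
50,0.005123371381
51,0.00558413128
52,0.006090809982
53,0.006647983704
54,0.007260684722
55,0.007934446821
56,0.00867535528
57,0.009490101827
58,0.01038604508
59,0.01137127702
60,0.01245469604
61,0.01364608736
62,0.01495621137
63,0.01639690085
64,0.01798116779
65,0.01972332096
66,0.02163909512
67,0.02374579313
68,0.02606244226
69,0.02860996599
70,0.03141137302
71,0.03449196507
72,0.03787956539
73,0.04160477008
74,0.04570122441
75,0.05020592668
76,0.05515956243
77,0.06060687184
78,0.06659705387
79,0.07318421059
80,0.0804278358
81,0.08839335241
82,0.09715270329
83,0.106785001
84,0.1173772426
85,0.1290250947
86,0.1418337585
87,0.1559189191
88,0.1714077907
89,0.1884402654
90,0.2071701771
91,0.2277666903
92,0.2504158285
93,0.2753221538
94,0.3027106151
95,0.332828579
96,0.3659480647
97,0.4023682004
98,0.4424179252
99,0.4864589596
100,0.5348890732
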