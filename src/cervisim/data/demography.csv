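age,monthly_death_prob,monthly_hysterectomy_prob
0,4.33436645435048e-05,0.0
1,4.348254262898088e-05,0.0
2,4.363298770238e-05,0.0
3,4.379596318582202e-05,0.0
4,4.3972512748902126e-05,0.0
5,4.41637669944539e-05,0.0
6,4.437095069920183e-05,0.0
7,4.45953906601515e-05,0.0
8,4.483852419256973e-05,0.0
9,4.510190833761918e-05,0.0
10,4.538722983704613e-05,0.0
11,4.569631593798196e-05,0.0
12,4.6031146099689835e-05,0.0
13,4.639386467542028e-05,0.0
14,4.678679465086599e-05,0.0
15,4.721245252825579e-05,0.0
16,4.767356445123383e-05,0.0
17,4.817308367333073e-05,0.0
18,4.8714209483935456e-05,0.0
19,4.9300407711450056e-05,0.0
20,4.9935432935854784e-05,1.5833621137106846e-05
21,5.062335255479056e-05,2.142665046556136e-05
22,5.136857285581442e-05,2.8639836241017846e-05
23,5.217586726413703e-05,3.781201264663192e-05
24,5.305040694647545e-05,4.9309767256922044e-05
25,5.399779396841886e-05,6.351567509532696e-05
26,5.502409721869217e-05,8.081176719842986e-05
27,5.6135891332020904e-05,0.00010155817056911598
28,5.7340298860730776e-05,0.00012606730215192208
29,5.864503596753057e-05,0.00015457453020850664
30,6.005846193368747e-05,0.00018720679145534103
31,6.158963280300522e-05,0.00022395121412299712
32,6.324835950699548e-05,0.00026462627557533036
33,6.504527084827405e-05,0.000308858342214835
34,6.69918817476356e-05,0.00035606652637343306
35,6.910066719922892e-05,0.0004054585911953401
36,7.138514241011862e-05,0.0004560401069489961
37,7.38599496469261e-05,0.0005066382125964441
38,7.654095235121172e-05,0.0005559402083713527
39,7.944533713621915e-05,0.0006025458854895804
40,8.259172432933948e-05,0.0006450311137597975
41,8.600028777983049e-05,0.0006820189100282814
42,8.969288471405434e-05,0.0007122531630392448
43,9.36931964877763e-05,0.0007346695436951656
44,9.802688115601033e-05,0.0007484579977157235
45,0.00010272173886194391,0.0007531116566323881
46,0.00010780789113251643,0.0007484579977157235
47,0.00011331797526037413,0.0007346695436951656
48,0.0001192873550576179,0.0007122531630392448
49,0.00012575434937445173,0.0006820189100282814
50,0.00013276047989996265,0.0006450311137597975
51,0.00014035073989615565,0.0006025458854895804
52,0.0001485738856570329,0.0005559402083713527
53,0.0001574827526477085,0.0005066382125964441
54,0.0001671345984490813,0.0004560401069489961
55,0.00017759147482310222,0.0004054585911953401
56,0.0001889206314219516,0.00035606652637343306
57,0.00020119495389181452,0.000308858342214835
58,0.00021449343936952303,0.00026462627557533036
59,0.00022890171264544623,0.00022395121412299712
60,0.0002445125865663256,0.00018720679145534103
61,0.00026142667058126623,0.00015457453020850664
62,0.00027975303169791577,0.00012606730215192208
63,0.00029960991251876123,0.00010155817056911598
64,0.00032112551146668,8.081176719842986e-05
65,0.00034443883080159665,6.351567509532696e-05
66,0.000369700598566558,4.9309767256922044e-05
67,0.0003970742712052777,3.781201264663192e-05
68,0.00042673712425644883,2.8639836241017846e-05
69,0.00045888143926753333,2.142665046556136e-05
70,0.0004937157958980753,1.5833621137106846e-05
71,0.0005314664790961876,0.0
72,0.0005723790122607042,0.0
73,0.00061671982844691,0.0
74,0.000664778092964502,0.0
75,0.0007168676921606165,0.0
76,0.0007733294048126726,0.0
77,0.0008345332743975309,0.0
78,0.0009008812025829149,0.0
79,0.0009728097866520402,0.0
80,0.00105079342625658,0.0
81,0.001135347727955316,0.0
82,0.0012270332394960226,0.0
83,0.0013264595498080345,0.0
84,0.0014342897952843714,0.0
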