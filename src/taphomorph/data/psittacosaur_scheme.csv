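id,description,pair,midline,excluded
1,Ventral tip of the rostral on midline,,1,0
2,Dorsalmost part of rostralmost nasal on midline,,1,0
3,Height of right nasal on skull roof,31,0,0
4,Rostral position of right naris (middle),32,0,0
5,Dorsal position of right naris (middle),33,0,0
6,Caudal position of right naris (middle),34,0,0
7,Ventral position of right naris (middle),35,0,0
8,Rostral position of right orbit (middle),36,0,0
9,Dorsal position of right orbit (middle),37,0,0
10,Caudal position of right orbit (middle),38,0,0
11,Ventral position of right orbit (middle),39,0,0
12,Height of right postorbital,40,0,0
13,Rostral position of right lateral temporal fenestra (middle),41,0,0
14,Dorsal position of right lateral temporal fenestra (middle),42,0,0
15,Caudal position of right lateral temporal fenestra (middle),43,0,0
16,Ventral position of right lateral temporal fenestra (middle),44,0,0
17,Ventral position of right jugal below orbit,45,0,1
18,Right quadratojugal at jugal contact,46,0,1
19,Postorbital eminence (right),47,0,0
20,Dorsal position of right quadrate,48,0,0
21,Ventral position of right quadrate,49,0,1
22,Middle of right quadrate on caudal aspect,50,0,0
23,Height of right side of skull on caudalmost point (squamosal),51,0,0
24,Lateralmost point of right jugal horn,52,0,0
25,Rostral position of right supratemporal fenestra (middle),53,0,0
26,Medial position of right supratemporal fenestra (middle),54,0,0
27,Caudal position of right supratemporal fenestra (middle),55,0,0
28,Lateral position of right supratemporal fenestra (middle),56,0,0
29,Sagittal crest at middle of supratemporal fenestrae,,1,0
30,Frontal suture at middle of orbit,,1,0
31,Height of left nasal on skull roof,3,0,0
32,Rostral position of left naris (middle),4,0,0
33,Dorsal position of left naris (middle),5,0,0
34,Caudal position of left naris (middle),6,0,0
35,Ventral position of left naris (middle),7,0,0
36,Rostral position of left orbit (middle),8,0,1
37,Dorsal position of left orbit (middle),9,0,0
38,Caudal position of left orbit (middle),10,0,0
39,Ventral position of left orbit (middle),11,0,1
40,Height of left postorbital,12,0,0
41,Rostral position of left lateral temporal fenestra (middle),13,0,0
42,Dorsal position of left lateral temporal fenestra (middle),14,0,0
43,Caudal position of left lateral temporal fenestra (middle),15,0,1
44,Ventral position of left lateral temporal fenestra (middle),16,0,1
45,Ventral position of left jugal below orbit,17,0,1
46,Left quadratojugal at jugal contact,18,0,1
47,Postorbital eminence (left),19,0,0
48,Dorsal position of left quadrate,20,0,1
49,Ventral position of left quadrate,21,0,1
50,Middle of left quadrate on caudal aspect,22,0,1
51,Height of left side of skull on caudalmost point (squamosal),23,0,0
52,Lateralmost point of left jugal horn,24,0,0
53,Rostral position of left supratemporal fenestra (middle),25,0,0
54,Medial position of left supratemporal fenestra (middle),26,0,0
55,Caudal position of left supratemporal fenestra (middle),27,0,0
56,Lateral position of left supratemporal fenestra (middle),28,0,0
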