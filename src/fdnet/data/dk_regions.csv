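id,name,abbreviation,lobe,hemisphere
1,Caudal anterior cingulate,CACg,frontal,L
2,Caudal anterior cingulate,CACg,frontal,R
3,Caudal middle frontal,CMF,frontal,L
4,Caudal middle frontal,CMF,frontal,R
5,Lateral orbital frontal,LOrF,frontal,L
6,Lateral orbital frontal,LOrF,frontal,R
7,Medial orbital frontal,MOrF,frontal,L
8,Medial orbital frontal,MOrF,frontal,R
9,Paracentral,PaC,frontal,L
10,Paracentral,PaC,frontal,R
11,Parsopercularis,Op,frontal,L
12,Parsopercularis,Op,frontal,R
13,Parsorbitalis,Or,frontal,L
14,Parsorbitalis,Or,frontal,R
15,Parstriangularis,Tr,frontal,L
16,Parstriangularis,Tr,frontal,R
17,Precentral,PreC,frontal,L
18,Precentral,PreC,frontal,R
19,Rostral anterior cingulate,RoACg,frontal,L
20,Rostral anterior cingulate,RoACg,frontal,R
21,Rostral middle frontal,RoMF,frontal,L
22,Rostral middle frontal,RoMF,frontal,R
23,Superior frontal,SF,frontal,L
24,Superior frontal,SF,frontal,R
25,Frontal pole,FPol,frontal,L
26,Frontal pole,FPol,frontal,R
27,Insula,Ins,frontal,L
28,Insula,Ins,frontal,R
29,Bankssts,B,temporal,L
30,Bankssts,B,temporal,R
31,Entorhinal,En,temporal,L
32,Entorhinal,En,temporal,R
33,Fusiform,Fu,temporal,L
34,Fusiform,Fu,temporal,R
35,Inferior temporal,IT,temporal,L
36,Inferior temporal,IT,temporal,R
37,Medial temporal,MT,temporal,L
38,Medial temporal,MT,temporal,R
39,Para hippocampal,PaH,temporal,L
40,Para hippocampal,PaH,temporal,R
41,Superior temporal,ST,temporal,L
42,Superior temporal,ST,temporal,R
43,Temporal pole,TPol,temporal,L
44,Temporal pole,TPol,temporal,R
45,Transverse temporal,TrT,temporal,L
46,Transverse temporal,TrT,temporal,R
47,Inferior parietal,IP,parietal,L
48,Inferior parietal,IP,parietal,R
49,Isthmus cingulate,IstCg,parietal,L
50,Isthmus cingulate,IstCg,parietal,R
51,Postcentral,PoC,parietal,L
52,Postcentral,PoC,parietal,R
53,Posterior cingulate,PoCg,parietal,L
54,Posterior cingulate,PoCg,parietal,R
55,Precuneus,PreCu,parietal,L
56,Precuneus,PreCu,parietal,R
57,Superior parietal,SP,parietal,L
58,Superior parietal,SP,parietal,R
59,Supra marginal,SM,parietal,L
60,Supra marginal,SM,parietal,R
61,Cuneus,Cu,occipital,L
62,Cuneus,Cu,occipital,R
63,Lateral occipital,LO,occipital,L
64,Lateral occipital,LO,occipital,R
65,Lingual,Lg,occipital,L
66,Lingual,Lg,occipital,R
67,Pericalcarine,PerCa,occipital,L
68,Pericalcarine,PerCa,occipital,R
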