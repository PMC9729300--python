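id,team,role,energy,stamina,pace,shooting,agility,teamwork
1,A,G,100,90,46,88,10,95
2,A,rCB,100,79,74,64,71,71
3,A,CB,100,76,65,61,66,69
4,A,lCB,100,61,94,72,84,78
5,A,rMF,100,78,80,69,80,85
6,A,rCMF,100,81,40,62,78,79
7,A,CMF,100,58,71,70,90,87
8,A,lCMF,100,66,65,84,82,86
9,A,lMF,100,84,84,94,90,83
10,A,rF,100,69,93,94,99,91
11,A,lF,100,65,93,73,88,77
12,B,G,100,88,55,73,10,95
13,B,rCB,100,94,83,75,85,85
14,B,CB,100,79,79,45,65,61
15,B,lCB,100,79,78,69,85,80
16,B,rMF,100,78,82,45,79,73
17,B,rCMF,100,72,52,86,85,92
18,B,CMF,100,68,75,81,91,89
19,B,lCMF,100,66,73,88,91,87
20,B,lMF,100,84,92,96,93,86
21,B,rF,100,83,97,93,91,89
22,B,lF,100,76,79,86,84,81
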