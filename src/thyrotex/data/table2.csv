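nodule_id,P1,P2,P3,DSS
1,10,10,5,8
2,15,25,5,16
3,15,5,5,14
4,50,50,20,27
5,90,95,0,84
6,0,20,70,22
7,75,70,70,20
8,10,10,10,9
9,45,50,20,1
10,5,5,0,0
11,95,80,80,28
12,50,30,20,16
13,30,30,20,3
14,0,0,0,0
15,95,30,90,27
16,15,20,15,5
17,10,50,5,0
18,5,15,0,0
19,1,5,0,0
20,5,20,5,7
21,0,5,0,0
22,10,10,5,3
23,2,15,5,0
24,70,75,50,66
25,70,10,60,8
26,1,5,0,0
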