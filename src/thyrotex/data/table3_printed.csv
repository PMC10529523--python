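nodule_id,P1,P2,P3
1,20,20,-60
2,-6.6,36,-220
3,6.6,-180,-180
4,46,46,-35
5,6.6,11.5,NA
6,NA,-10,68.57
7,73.3,71.4,71.42
8,10,10,10
9,97.7,98,95
10,100,100,NA
11,70.5,65,65
12,68,46.6,20
13,90,90,85
14,0,0,0
15,71.5,10,70
16,66.6,75,66.6
17,100,100,100
18,100,100,NA
19,100,100,0
20,-40,65,-40
21,0,100,0
22,70,70,40
23,100,100,100
24,5.7,12,-32
25,88.5,20,86.6
26,100,100,0
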