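id,sensory_group,lt,p,pp,d,pr,fma_ue,months_post_stroke,age_years,gender,affected_side,handedness
1,severe,0,1,1,NA,NA,1,66,71,F,L,R
2,severe,0,1,1,NA,1,8,21,54,M,L,L
3,severe,1,1,1,NA,0,9,212,66,F,R,R
4,severe,1,1,1,0,1,10,6,64,M,R,R
5,severe,1,1,1,NA,1,20,142,68,M,L,L
6,severe,1,1,1,NA,1,26,15,72,M,L,L
7,severe,1,2,2,1,1,62,7,77,M,L,L
8,mild,1,2,2,1,2,9,71,59,M,L,L
9,mild,1,2,2,1,2,10,81,48,M,L,L
10,mild,2,2,2,1,2,10,6,93,F,R,R
11,mild,2,2,2,1,2,54,26,67,M,R,R
12,mild,2,2,2,1,2,56,11,56,M,L,L
13,mild,1,2,2,1,2,59,53,50,F,R,R
14,mild,2,2,2,1,2,60,11,61,F,R,R
15,mild,2,2,2,1,2,63,35,76,F,L,L
16,mild,2,2,2,1,2,63,10,78,F,R,R
17,mild,2,2,2,1,2,64,23,65,M,L,L
18,mild,2,2,2,1,2,64,6,70,F,R,R
19,mild,2,2,2,1,2,64,6,75,F,L,R
20,none,2,2,2,2,2,11,6,52,F,R,R
21,none,2,2,2,2,2,13,82,64,M,L,L
22,none,2,2,2,2,2,20,6,77,M,L,R
23,none,2,2,2,2,2,39,50,62,M,R,R
24,none,2,2,2,2,2,48,35,50,M,R,R
25,none,2,2,2,2,2,58,75,55,M,L,L
26,none,2,2,2,2,2,59,41,49,F,L,L
27,none,2,2,2,2,2,60,6,73,M,L,R
28,none,2,2,2,2,2,66,67,68,F,R,R
29,none,2,2,2,2,2,66,10,57,M,L,L
30,none,2,2,2,2,2,66,88,48,M,R,R
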