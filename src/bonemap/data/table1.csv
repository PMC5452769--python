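experiment,specimen,side,age,sex,surgeon,dm,ss,fn,group
1,K01,R,88,M,1,U,I,I,unguided
2,K02,R,98,F,1,U,U,I,unguided
3,K03,R,79,F,2,U,U,I,unguided
4,K04,R,78,F,3,U,S,I,unguided
5,K05,R,50,F,1,U,I,I,unguided
6,K06,R,84,M,1,I,I,I,guided
7,K07,R,91,F,1,I,I,I,guided
8,K06,L,84,M,2,U,I,I,guided
9,K08,R,83,M,2,I,I,I,guided
10,K09,R,78,F,1,S,I,I,guided
11,K09,L,78,F,2,S,I,I,guided
12,K04,L,78,F,2,I,I,I,guided
13,K10,R,83,F,1,S,I,I,guided
14,K11,R,86,M,2,U,I,I,guided
15,K11,L,86,M,2,S,I,I,guided
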