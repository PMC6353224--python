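index,hoxA,hoxB,pou,ebox,tata,occupancy,q_factors,w_factors,h_factors
1,empty,empty,empty,empty,empty,empty,-,-,-
2,A1,empty,empty,empty,empty,A1,qA1,-,-
3,empty,empty,A2,empty,empty,A2,qA2,-,-
4,empty,B1,empty,empty,empty,B1,qB1,-,-
5,empty,empty,B2,empty,empty,B2,qB2,-,-
6,A1,B1,empty,empty,empty,A1+B1,qA1+qB1,-,-
7,A1,empty,A2,empty,empty,A1+A2,qA1+qA2,wA1A2,-
8,A1,empty,B2,empty,empty,A1+B2,qA1+qB2,wA1B2,-
9,empty,B1,B2,empty,empty,B1+B2,qB1+qB2,wB1B2,-
10,empty,B1,A2,empty,empty,B1+A2,qA2+qB1,wB1A2,-
11,A1,B1,A2,empty,empty,A1+B1+A2,qA1+qA2+qB1,wA1A2+wB1A2,-
12,A1,B1,B2,empty,empty,A1+B1+B2,qA1+qB1+qB2,wA1B2+wB1B2,-
13,empty,B1,B2,C,empty,B1+B2+C,qB1+qB2+qC,wB1B2,h3+hB
14,A1,empty,A2,C,empty,A1+A2+C,qA1+qA2+qC,wA1A2,h3+hA
15,A1,B1,A2,C,empty,A1+B1+A2+C,qA1+qA2+qB1+qC,wA1A2+wB1A2,h3+hA
16,A1,B1,B2,C,empty,A1+B1+B2+C,qA1+qB1+qB2+qC,wA1B2+wB1B2,h3+hB
17,empty,empty,B2,C,empty,B2+C,qB2+qC,-,h3
18,empty,empty,A2,C,empty,A2+C,qA2+qC,-,h3
19,A1,empty,B2,C,empty,A1+B2+C,qA1+qB2+qC,wA1B2,h3
20,empty,B1,A2,C,empty,B1+A2+C,qA2+qB1+qC,wB1A2,h3
21,empty,empty,empty,C,empty,C,qC,-,h1
22,A1,empty,empty,C,empty,A1+C,qA1+qC,-,h2
23,empty,B1,empty,C,empty,B1+C,qB1+qC,-,h2
24,A1,B1,empty,C,empty,A1+B1+C,qA1+qB1+qC,-,h2
25,empty,empty,empty,empty,R,R,qR,-,-
26,A1,empty,empty,empty,R,A1+R,qA1+qR,-,-
27,empty,empty,A2,empty,R,A2+R,qA2+qR,-,-
28,empty,B1,empty,empty,R,B1+R,qB1+qR,-,-
29,empty,empty,B2,empty,R,B2+R,qB2+qR,-,-
30,A1,B1,empty,empty,R,A1+B1+R,qA1+qB1+qR,-,-
31,A1,empty,A2,empty,R,A1+A2+R,qA1+qA2+qR,wA1A2,-
32,A1,empty,B2,empty,R,A1+B2+R,qA1+qB2+qR,wA1B2,-
33,empty,B1,B2,empty,R,B1+B2+R,qB1+qB2+qR,wB1B2,-
34,empty,B1,A2,empty,R,B1+A2+R,qA2+qB1+qR,wB1A2,-
35,A1,B1,A2,empty,R,A1+B1+A2+R,qA1+qA2+qB1+qR,wA1A2+wB1A2,-
36,A1,B1,B2,empty,R,A1+B1+B2+R,qA1+qB1+qB2+qR,wA1B2+wB1B2,-
37,empty,B1,B2,C,R,B1+B2+C+R,qB1+qB2+qC+qR,wB1B2+wCR,h3+hB
38,A1,empty,A2,C,R,A1+A2+C+R,qA1+qA2+qC+qR,wA1A2+wCR,h3+hA
39,A1,B1,A2,C,R,A1+B1+A2+C+R,qA1+qA2+qB1+qC+qR,wA1A2+wB1A2+wCR,h3+hA
40,A1,B1,B2,C,R,A1+B1+B2+C+R,qA1+qB1+qB2+qC+qR,wA1B2+wB1B2+wCR,h3+hB
41,empty,empty,B2,C,R,B2+C+R,qB2+qC+qR,wCR,h3
42,empty,empty,A2,C,R,A2+C+R,qA2+qC+qR,wCR,h3
43,A1,empty,B2,C,R,A1+B2+C+R,qA1+qB2+qC+qR,wA1B2+wCR,h3
44,empty,B1,A2,C,R,B1+A2+C+R,qA2+qB1+qC+qR,wB1A2+wCR,h3
45,empty,empty,empty,C,R,C+R,qC+qR,-,h1
46,A1,empty,empty,C,R,A1+C+R,qA1+qC+qR,wCR,h2
47,empty,B1,empty,C,R,B1+C+R,qB1+qC+qR,wCR,h2
48,A1,B1,empty,C,R,A1+B1+C+R,qA1+qB1+qC+qR,wCR,h2
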