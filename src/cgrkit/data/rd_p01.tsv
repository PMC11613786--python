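Segment	Start	End	Type	Method
B	14851664	24610783	DEL	aCGH,srGS,lrGS
D	25290884	25303024	DUP	srGS,lrGS
F	25713476	25865801	DUP	aCGH,srGS,lrGS
H	26642007	26776417	DUP	aCGH,srGS,lrGS
J	26799626	26934775	DUP	srGS,lrGS
L	27417474	27809326	DEL	aCGH,srGS,lrGS
N	29463413	29673698	DUP	aCGH,srGS,lrGS*
P	31172424	31179763	DUP	srGS,lrGS
R	31653158	34549575	DEL	aCGH,srGS,lrGS*
T	36841751	37237424	DEL	aCGH,srGS,lrGS
V	42358829	42440338	DUP	srGS,lrGS
X	43489001	43505695	DUP	srGS
Z	44694487	44862839	DUP	aCGH,srGS,lrGS
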