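Segment	Start	End	Type	Method
B	23765839	24915464	DUP	aCGH,srGS,lrGS
D	29450256	30482559	DUP	aCGH,srGS,lrGS
F	30739588	32660588	DUP	aCGH,srGS,lrGS
H	33708435	35258903	DUP	aCGH,srGS,lrGS
J	37439494	38243038	DUP	aCGH,srGS,lrGS
L	41208203	45090682	DUP	aCGH,srGS,lrGS,FISH
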