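Segment	Start	End	Type	Method
Tel	pter	329999	DEL	OGM
B	532439	2754000	DEL	OGM
C	2754001	3885184	INV	srGS*,lrGS*,OGM
D	3885185	8276221	DEL	OGM*
F	40385031	41802370	DEL	aCGH,srGS,lrGS,OGM
G	41802371	42715704	INV	srGS,lrGS,OGM
H	42715705	45090682	DEL	aCGH,srGS,lrGS,OGM,FISH
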