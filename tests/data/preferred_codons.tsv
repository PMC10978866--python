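aa	codon
A	GCC
C	TGC
D	GAC
E	GAG
F	TTC
G	GGC
H	CAC
I	ATC
K	AAG
L	CTG
M	ATG
N	AAC
P	CCC
Q	CAG
R	AGA
S	AGC
T	ACC
V	GTG
W	TGG
Y	TAC
*	TGA
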