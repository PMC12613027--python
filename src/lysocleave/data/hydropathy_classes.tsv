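residue	class
A	Φ
C	Φ
D	ζ
E	ζ
F	Φ
G	M
H	M
I	Φ
K	ζ
L	Φ
M	Φ
N	ζ
P	M
Q	ζ
R	ζ
S	M
T	M
V	Φ
W	Φ
Y	M
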