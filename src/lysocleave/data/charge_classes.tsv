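residue	class
A	N
C	N
D	-
E	-
F	N
G	N
H	+
I	N
K	+
L	N
M	N
N	N
P	N
Q	N
R	+
S	N
T	N
V	N
W	N
Y	N
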