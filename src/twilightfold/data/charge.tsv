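# name: charge
# provenance: formal charge at neutral pH: K,R=+1; D,E=-1; H=0 (convention)
# normalization: raw
residue	value
A	0.0
C	0.0
D	-1.0
E	-1.0
F	0.0
G	0.0
H	0.0
I	0.0
K	1.0
L	0.0
M	0.0
N	0.0
P	0.0
Q	0.0
R	1.0
S	0.0
T	0.0
V	0.0
W	0.0
Y	0.0
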