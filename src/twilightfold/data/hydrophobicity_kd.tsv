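# name: hydrophobicity
# provenance: Kyte-Doolittle hydropathy, min-max rescaled to [0,1]
# normalization: unit-interval
residue	value
A	0.700000
C	0.777778
D	0.111111
E	0.111111
F	0.811111
G	0.455556
H	0.144444
I	1.000000
K	0.066667
L	0.922222
M	0.711111
N	0.111111
P	0.322222
Q	0.111111
R	0.000000
S	0.411111
T	0.422222
V	0.966667
W	0.400000
Y	0.355556
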