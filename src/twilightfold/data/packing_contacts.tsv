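# name: packing
# provenance: expected number of residues within 8 A per residue type (Galzitskaya-type packing scale; transcribed, approximate)
# normalization: raw
residue	value
A	21.40
C	24.00
D	18.02
E	17.76
F	25.89
G	19.42
H	20.89
I	25.25
K	16.64
L	24.46
M	24.14
N	17.98
P	17.48
Q	18.60
R	18.72
S	19.02
T	19.83
V	24.45
W	25.29
Y	24.10
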