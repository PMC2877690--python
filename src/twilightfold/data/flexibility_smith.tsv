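# name: flexibility
# provenance: B-factor-derived flexibility scale of Smith et al. (transcribed, approximate)
# normalization: raw
residue	value
A	-0.605
C	-0.692
D	-0.279
E	-0.160
F	-0.718
G	-0.537
H	-0.662
I	-0.682
K	-0.043
L	-0.670
M	-0.626
N	-0.381
P	-0.271
Q	-0.368
R	-0.448
S	-0.424
T	-0.436
V	-0.669
W	-0.727
Y	-0.721
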