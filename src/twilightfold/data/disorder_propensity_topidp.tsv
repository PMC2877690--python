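# name: disorder_propensity_surrogate
# provenance: TOP-IDP disorder propensity (Campen et al. 2008), min-max normalized to [0,1]; surrogate profile source, not a VSL2 reimplementation
# normalization: unit-interval
residue	value
A	0.504543
C	0.483164
D	0.575094
E	0.865847
F	0.099947
G	0.561197
H	0.634420
I	0.212720
K	0.785676
L	0.298236
M	0.260289
N	0.476216
P	1.000000
Q	0.642437
R	0.568680
S	0.654730
T	0.504009
V	0.407803
W	0.000000
Y	0.199893
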