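# name: pairwise_energy_synthetic
# provenance: synthetic calibrated stand-in for a statistical contact-energy predictor matrix: P_ij = -(s_i+s_j)/2 + 0.4*q_i*q_j with hand-set stickiness s and formal charges q; calibrated so folded-like compositions score near -0.6 a.e.u. and disordered-like near -0.35
# units: a.e.u.
residue	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-0.4000	-0.7000	-0.2500	-0.2250	-0.6500	-0.3750	-0.4250	-0.6500	-0.2250	-0.6250	-0.5750	-0.3500	-0.2500	-0.3000	-0.3250	-0.3000	-0.3750	-0.6000	-0.6750	-0.5500
C	-0.7000	-1.0000	-0.5500	-0.5250	-0.9500	-0.6750	-0.7250	-0.9500	-0.5250	-0.9250	-0.8750	-0.6500	-0.5500	-0.6000	-0.6250	-0.6000	-0.6750	-0.9000	-0.9750	-0.8500
D	-0.2500	-0.5500	0.3000	0.3250	-0.5000	-0.2250	-0.2750	-0.5000	-0.4750	-0.4750	-0.4250	-0.2000	-0.1000	-0.1500	-0.5750	-0.1500	-0.2250	-0.4500	-0.5250	-0.4000
E	-0.2250	-0.5250	0.3250	0.3500	-0.4750	-0.2000	-0.2500	-0.4750	-0.4500	-0.4500	-0.4000	-0.1750	-0.0750	-0.1250	-0.5500	-0.1250	-0.2000	-0.4250	-0.5000	-0.3750
F	-0.6500	-0.9500	-0.5000	-0.4750	-0.9000	-0.6250	-0.6750	-0.9000	-0.4750	-0.8750	-0.8250	-0.6000	-0.5000	-0.5500	-0.5750	-0.5500	-0.6250	-0.8500	-0.9250	-0.8000
G	-0.3750	-0.6750	-0.2250	-0.2000	-0.6250	-0.3500	-0.4000	-0.6250	-0.2000	-0.6000	-0.5500	-0.3250	-0.2250	-0.2750	-0.3000	-0.2750	-0.3500	-0.5750	-0.6500	-0.5250
H	-0.4250	-0.7250	-0.2750	-0.2500	-0.6750	-0.4000	-0.4500	-0.6750	-0.2500	-0.6500	-0.6000	-0.3750	-0.2750	-0.3250	-0.3500	-0.3250	-0.4000	-0.6250	-0.7000	-0.5750
I	-0.6500	-0.9500	-0.5000	-0.4750	-0.9000	-0.6250	-0.6750	-0.9000	-0.4750	-0.8750	-0.8250	-0.6000	-0.5000	-0.5500	-0.5750	-0.5500	-0.6250	-0.8500	-0.9250	-0.8000
K	-0.2250	-0.5250	-0.4750	-0.4500	-0.4750	-0.2000	-0.2500	-0.4750	0.3500	-0.4500	-0.4000	-0.1750	-0.0750	-0.1250	0.2500	-0.1250	-0.2000	-0.4250	-0.5000	-0.3750
L	-0.6250	-0.9250	-0.4750	-0.4500	-0.8750	-0.6000	-0.6500	-0.8750	-0.4500	-0.8500	-0.8000	-0.5750	-0.4750	-0.5250	-0.5500	-0.5250	-0.6000	-0.8250	-0.9000	-0.7750
M	-0.5750	-0.8750	-0.4250	-0.4000	-0.8250	-0.5500	-0.6000	-0.8250	-0.4000	-0.8000	-0.7500	-0.5250	-0.4250	-0.4750	-0.5000	-0.4750	-0.5500	-0.7750	-0.8500	-0.7250
N	-0.3500	-0.6500	-0.2000	-0.1750	-0.6000	-0.3250	-0.3750	-0.6000	-0.1750	-0.5750	-0.5250	-0.3000	-0.2000	-0.2500	-0.2750	-0.2500	-0.3250	-0.5500	-0.6250	-0.5000
P	-0.2500	-0.5500	-0.1000	-0.0750	-0.5000	-0.2250	-0.2750	-0.5000	-0.0750	-0.4750	-0.4250	-0.2000	-0.1000	-0.1500	-0.1750	-0.1500	-0.2250	-0.4500	-0.5250	-0.4000
Q	-0.3000	-0.6000	-0.1500	-0.1250	-0.5500	-0.2750	-0.3250	-0.5500	-0.1250	-0.5250	-0.4750	-0.2500	-0.1500	-0.2000	-0.2250	-0.2000	-0.2750	-0.5000	-0.5750	-0.4500
R	-0.3250	-0.6250	-0.5750	-0.5500	-0.5750	-0.3000	-0.3500	-0.5750	0.2500	-0.5500	-0.5000	-0.2750	-0.1750	-0.2250	0.1500	-0.2250	-0.3000	-0.5250	-0.6000	-0.4750
S	-0.3000	-0.6000	-0.1500	-0.1250	-0.5500	-0.2750	-0.3250	-0.5500	-0.1250	-0.5250	-0.4750	-0.2500	-0.1500	-0.2000	-0.2250	-0.2000	-0.2750	-0.5000	-0.5750	-0.4500
T	-0.3750	-0.6750	-0.2250	-0.2000	-0.6250	-0.3500	-0.4000	-0.6250	-0.2000	-0.6000	-0.5500	-0.3250	-0.2250	-0.2750	-0.3000	-0.2750	-0.3500	-0.5750	-0.6500	-0.5250
V	-0.6000	-0.9000	-0.4500	-0.4250	-0.8500	-0.5750	-0.6250	-0.8500	-0.4250	-0.8250	-0.7750	-0.5500	-0.4500	-0.5000	-0.5250	-0.5000	-0.5750	-0.8000	-0.8750	-0.7500
W	-0.6750	-0.9750	-0.5250	-0.5000	-0.9250	-0.6500	-0.7000	-0.9250	-0.5000	-0.9000	-0.8500	-0.6250	-0.5250	-0.5750	-0.6000	-0.5750	-0.6500	-0.8750	-0.9500	-0.8250
Y	-0.5500	-0.8500	-0.4000	-0.3750	-0.8000	-0.5250	-0.5750	-0.8000	-0.3750	-0.7750	-0.7250	-0.5000	-0.4000	-0.4500	-0.4750	-0.4500	-0.5250	-0.7500	-0.8250	-0.7000
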