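#shapestring-torsion-regions	v1
letter	phi_lo	phi_hi	psi_lo	psi_hi	gly_only	core
G	0	180	-180	180	1	1
A	-160	-20	-120	50	0	1
K	-160	-20	50	100	0	1
S	-180	-100	100	180	0	1
S	-180	-100	-180	-120	0	0
R	-100	0	100	180	0	1
U	-100	0	-180	-120	0	1
V	-180	-160	-120	100	0	1
V	-20	0	-120	100	0	0
T	0	180	-180	180	0	1
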