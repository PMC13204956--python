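name	x	y
Fp1	-0.309	0.951
Fp2	0.309	0.951
F7	-0.809	0.588
F3	-0.400	0.480
Fz	0.000	0.450
F4	0.400	0.480
F8	0.809	0.588
T3	-0.950	0.000
C3	-0.450	0.000
Cz	0.000	0.000
C4	0.450	0.000
T4	0.950	0.000
T5	-0.809	-0.588
P3	-0.400	-0.480
Pz	0.000	-0.450
P4	0.400	-0.480
T6	0.809	-0.588
O1	-0.309	-0.951
O2	0.309	-0.951
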