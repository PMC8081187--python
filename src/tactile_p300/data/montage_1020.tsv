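name	x	y
Fp1	-0.31	0.95
Fp2	0.31	0.95
F7	-0.81	0.59
F3	-0.45	0.55
Fz	0.00	0.72
F4	0.45	0.55
F8	0.81	0.59
FC5	-0.59	0.28
FC1	-0.23	0.33
FC2	0.23	0.33
FC6	0.59	0.28
T7	-1.00	0.00
C3	-0.50	0.00
Cz	0.00	0.00
C4	0.50	0.00
T8	1.00	0.00
TP9	-0.95	-0.31
CP5	-0.59	-0.28
CP1	-0.23	-0.33
CP2	0.23	-0.33
CP6	0.59	-0.28
TP10	0.95	-0.31
P7	-0.81	-0.59
P3	-0.45	-0.55
Pz	0.00	-0.72
P4	0.45	-0.55
P8	0.81	-0.59
O1	-0.31	-0.95
Oz	0.00	-1.00
O2	0.31	-0.95
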