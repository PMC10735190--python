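label,x,y
Fp1,-0.2797,0.8430
Fp2,0.2797,0.8430
F3,-0.3737,0.4400
F4,0.3737,0.4400
Fz,0.0000,0.4161
F7,-0.7481,0.5003
F8,0.7481,0.5003
C3,-0.4086,-0.0228
C4,0.4086,-0.0228
Cz,0.0000,0.0000
P3,-0.3021,-0.3908
P4,0.3021,-0.3908
Pz,0.0000,-0.3505
O1,-0.1951,-0.6930
O2,0.1951,-0.6930
T3,-0.8455,-0.1084
T4,0.8455,-0.1084
T5,-0.5752,-0.5325
T6,0.5752,-0.5325
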