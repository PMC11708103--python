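pid,X1,X2,X3,X4,X5,X6,X7,X8,X9,X10
P1,0.50,0.33,0.33,0.42,0.25,0.50,0.50,0.25,0.25,1.00
P2,0.75,0.33,0.67,0.75,0.88,1.00,1.00,0.75,0.50,1.00
P3,0.75,0.33,0.67,0.50,0.38,0.50,0.75,0.50,0.25,1.00
P4,1.00,0.33,0.33,0.83,0.88,1.00,1.00,0.25,0.75,1.00
P5,0.50,0.33,0.33,0.42,0.25,0.50,0.75,0.25,0.50,1.00
P6,0.50,0.33,0.33,0.50,0.38,0.50,0.50,1.00,0.75,1.00
P7,0.75,0.33,0.67,0.42,0.38,1.00,0.75,0.50,0.25,1.00
P8,0.50,0.33,0.33,0.17,0.13,0.50,0.50,0.50,0.25,1.00
P9,1.00,0.33,0.33,0.67,0.50,0.50,1.00,0.50,0.25,1.00
P10,1.00,0.33,0.33,0.50,0.63,0.50,1.00,0.25,0.25,1.00
P11,0.75,0.33,0.33,0.58,0.63,1.00,1.00,0.50,0.75,1.00
P12,1.00,0.33,0.33,0.50,0.75,1.00,1.00,0.75,0.25,1.00
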