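pid,pmc,depression,level,rank
P1,4.33,5.67,Poor,12
P2,7.63,2.37,Excellent,1
P3,5.63,4.37,Acceptable,10
P4,7.37,2.63,Excellent,2
P5,4.83,5.17,Poor,11
P6,5.79,4.21,Acceptable,8
P7,6.05,3.95,Good,7
P8,4.21,5.79,Poor,13
P9,6.08,3.92,Good,6
P10,5.79,4.21,Acceptable,9
P11,6.87,3.13,Good,4
P12,6.91,3.09,Good,3
P13,6.55,3.45,Good,5
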