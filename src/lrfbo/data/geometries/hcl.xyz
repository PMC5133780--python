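2
B3LYP(VWN5)/6-311G** optimized E=-460.81848550 charge=0 multiplicity=1
H         0.0000000000       0.0000000000       0.0000000000
Cl        0.0000000000       0.0000000000       1.2854597038
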