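2
B3LYP(VWN5)/6-311G** optimized E=-100.44077452 charge=0 multiplicity=1
H         0.0000000000       0.0000000000       0.0000000000
F         0.0000000000       0.0000000000       0.9202718109
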