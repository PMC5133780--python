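3
B3LYP(VWN5)/6-311G** optimized E=-76.42050937 charge=0 multiplicity=1
O         0.0000000000       0.0000000000       0.0000000000
H         0.0000000000       0.7533346022       0.5993371802
H         0.0000000000      -0.7533346022       0.5993371802
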