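15
idealized planar all-trans charge=0 multiplicity=1
O         0.0000000000       0.0000000000       0.0000000000
C         1.1777945491      -0.6800000000       0.0000000000
C         2.3382685902      -0.0100000000       0.0000000000
C         3.5940054257      -0.7350000000       0.0000000000
C         4.7544794668      -0.0650000000       0.0000000000
C         6.0102163023      -0.7900000000       0.0000000000
C         7.1706903433      -0.1200000000       0.0000000000
H         0.1684387323       0.9552635204       0.0000000000
H         1.1777945491      -1.7600000000       0.0000000000
H         2.3382685902       1.0700000000       0.0000000000
H         3.5940054257      -1.8150000000       0.0000000000
H         4.7544794668       1.0150000000       0.0000000000
H         6.0102163023      -1.8700000000       0.0000000000
H         8.1152796270      -0.6435943899       0.0000000000
H         7.1895389423       0.9598355108       0.0000000000
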