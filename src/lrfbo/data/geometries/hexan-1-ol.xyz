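21
MMFF94 relaxed all-trans charge=0 multiplicity=1
O         3.6802409550       1.0411851168      -0.0974088890
C         2.3766354117       0.5898581692      -0.4440224315
C         1.8366422145      -0.3122271151       0.6587541266
C         0.4868483256      -0.9483531274       0.3259724709
C        -0.6489482542       0.0697446237       0.2037576742
C        -1.9926318194      -0.6247084438      -0.0222902010
C        -3.1256454274       0.3813798713      -0.1478877975
H         3.6068375679       1.5331537056       0.7381756179
H         1.7442409865       1.4688357918      -0.5981585177
H         2.4500095327       0.0467029121      -1.3911291144
H         2.5668784446      -1.1081722958       0.8528534221
H         1.7659376316       0.2543896067       1.5956110314
H         0.5709525013      -1.5232905455      -0.6042760720
H         0.2416347764      -1.6655748018       1.1191205733
H        -0.4536129729       0.7522096972      -0.6309988588
H        -0.6985173978       0.6768353521       1.1157517169
H        -1.9487278459      -1.2327270385      -0.9333982939
H        -2.2063307876      -1.3037580471       0.8113298658
H        -2.9593803387       1.0559908376      -0.9938127521
H        -3.2166769903       0.9850902330       0.7607240901
H        -4.0763865134      -0.1365645019      -0.3083027478
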