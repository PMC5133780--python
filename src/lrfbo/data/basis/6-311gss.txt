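! 6-311G** triple-split-valence basis with polarization on all atoms
! (Krishnan-Binkley-Seeger-Pople for H-F; McLean-Chandler sp set plus a
! d polarization function for Cl). Shared-exponent sp blocks are written
! as separate S and P shells. Normalized-primitive coefficient convention.
element H
S 3
  33.8650000   0.0254938
  5.09479000   0.1903730
  1.15879000   0.8521610
S 1
  0.32584000   1.0000000
S 1
  0.10274100   1.0000000
P 1
  0.75000000   1.0000000
end
element C
S 6
  4563.24000   0.00196665
  682.024000   0.0152306
  154.973000   0.0761269
  44.4553000   0.2608010
  13.0290000   0.6164620
  1.82773000   0.2210060
S 3
  20.9642000   0.1146600
  4.80331000   0.9199990
  1.45933000  -0.00303068
P 3
  20.9642000   0.0402487
  4.80331000   0.2375940
  1.45933000   0.8158540
S 1
  0.48345600   1.0000000
P 1
  0.48345600   1.0000000
S 1
  0.14558500   1.0000000
P 1
  0.14558500   1.0000000
D 1
  0.62600000   1.0000000
end
element N
S 6
  6293.48000   0.00196979
  949.044000   0.0149613
  218.776000   0.0735006
  63.6916000   0.2489370
  18.8282000   0.6024600
  2.72023000   0.2562020
S 3
  30.6331000   0.1119060
  7.02614000   0.9216660
  2.11205000  -0.00256919
P 3
  30.6331000   0.0383119
  7.02614000   0.2374030
  2.11205000   0.8175920
S 1
  0.68400900   1.0000000
P 1
  0.68400900   1.0000000
S 1
  0.20087800   1.0000000
P 1
  0.20087800   1.0000000
D 1
  0.91300000   1.0000000
end
element O
S 6
  8588.50000   0.00189515
  1297.23000   0.0143859
  299.296000   0.0707320
  87.3771000   0.2400010
  25.6789000   0.5947970
  3.74004000   0.2808020
S 3
  42.1175000   0.1138890
  9.62837000   0.9208110
  2.85332000  -0.00327447
P 3
  42.1175000   0.0365114
  9.62837000   0.2371530
  2.85332000   0.8197020
S 1
  0.90566100   1.0000000
P 1
  0.90566100   1.0000000
S 1
  0.25561100   1.0000000
P 1
  0.25561100   1.0000000
D 1
  1.29200000   1.0000000
end
element F
S 6
  11427.1000   0.00180093
  1722.35000   0.0137419
  395.746000   0.0681334
  115.139000   0.2333250
  33.6026000   0.5890860
  4.91901000   0.2995050
S 3
  55.4441000   0.1145360
  12.6323000   0.9205120
  3.71756000  -0.00337804
P 3
  55.4441000   0.0354609
  12.6323000   0.2374510
  3.71756000   0.8204580
S 1
  1.16545000   1.0000000
P 1
  1.16545000   1.0000000
S 1
  0.32189200   1.0000000
P 1
  0.32189200   1.0000000
D 1
  1.75000000   1.0000000
end
element Cl
S 6
  105819.000   0.0007380
  15872.0000   0.0057180
  3619.65000   0.0294950
  1030.80000   0.1172860
  339.908000   0.3629490
  124.538000   0.5841490
S 3
  124.538000   0.1341770
  49.5135000   0.6242500
  20.8056000   0.2917560
S 1
  6.58346000   1.0000000
S 1
  2.56468000   1.0000000
S 1
  0.55976300   1.0000000
S 1
  0.18327300   1.0000000
P 5
  589.776000   0.0023910
  139.849000   0.0185040
  45.1413000   0.0813770
  16.8733000   0.2215520
  6.74110000   0.7725690
P 2
  6.74110000  -1.5722440
  2.57113000   0.9923890
P 1
  0.77755000   1.0000000
P 1
  0.21003300   1.0000000
P 1
  0.06095700   1.0000000
D 1
  0.75000000   1.0000000
end
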