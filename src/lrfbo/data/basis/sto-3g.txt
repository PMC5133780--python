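! STO-3G minimal basis (Hehre-Stewart-Pople least-squares Gaussian
! expansions of Slater orbitals with standard molecular zeta exponents).
! Coefficients are in the normalized-primitive convention.
element H
S 3
  3.42525091   0.15432897
  0.62391373   0.53532814
  0.16885540   0.44463454
end
element C
S 3
  71.6168370   0.15432897
  13.0450960   0.53532814
  3.53051220   0.44463454
S 3
  2.94124940  -0.09996723
  0.68348310   0.39951283
  0.22228990   0.70011547
P 3
  2.94124940   0.15591627
  0.68348310   0.60768372
  0.22228990   0.39195739
end
element N
S 3
  99.1061690   0.15432897
  18.0523120   0.53532814
  4.88566020   0.44463454
S 3
  3.78045590  -0.09996723
  0.87849660   0.39951283
  0.28571440   0.70011547
P 3
  3.78045590   0.15591627
  0.87849660   0.60768372
  0.28571440   0.39195739
end
element O
S 3
  130.7093200  0.15432897
  23.8088610   0.53532814
  6.44360830   0.44463454
S 3
  5.03315130  -0.09996723
  1.16959610   0.39951283
  0.38038900   0.70011547
P 3
  5.03315130   0.15591627
  1.16959610   0.60768372
  0.38038900   0.39195739
end
element F
S 3
  166.6791300  0.15432897
  30.3608120   0.53532814
  8.21682070   0.44463454
S 3
  6.46480320  -0.09996723
  1.50228120   0.39951283
  0.48858850   0.70011547
P 3
  6.46480320   0.15591627
  1.50228120   0.60768372
  0.48858850   0.39195739
end
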