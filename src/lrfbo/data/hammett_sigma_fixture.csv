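# Illustrative Hammett substituent-constant fixture (standard Hansch-type
# sigma_m / sigma_p values, rounded; NOT a curated compilation -- shipped only
# so examples and tests have a realistic small table to regress against).
substituent,position,sigma
H,none,0.00
CH3,meta,-0.07
CH3,para,-0.17
C2H5,para,-0.15
OCH3,meta,0.12
OCH3,para,-0.27
OH,meta,0.12
OH,para,-0.37
F,meta,0.34
F,para,0.06
Cl,meta,0.37
Cl,para,0.23
Br,meta,0.39
Br,para,0.23
CN,meta,0.56
CN,para,0.66
NO2,meta,0.71
NO2,para,0.78
CF3,meta,0.43
CF3,para,0.54
NH2,meta,-0.16
NH2,para,-0.66
COCH3,meta,0.38
COCH3,para,0.50
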