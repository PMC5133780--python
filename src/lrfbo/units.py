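"""Unit constants (CODATA 2018)."""

BOHR_RADIUS_ANGSTROM = 0.529177210903
ANGSTROM_TO_BOHR = 1.0 / BOHR_RADIUS_ANGSTROM  # = 1.8897261246...
HARTREE_TO_EV = 27.211386245988
DEBYE_PER_AU = 2.541746473
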