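{
  "_comment": [
    "Single-zeta Slater shell descriptions for the neutral atoms used by the",
    "package (H, C, N, O).  Orbital exponents are the classic single-zeta",
    "SCF-optimized values (Clementi & Raimondi tabulation) in bohr^-1; shells",
    "are listed as [principal quantum number, exponent, occupancy].  The",
    "density of a shell with orbital r^(nq-1) exp(-zeta r) is",
    "r^(2 nq - 2) exp(-2 zeta r).  Deformation radial powers n_l (l = 0..4)",
    "and exponents follow common multipole-refinement defaults for first-row",
    "elements; they are package defaults, user-overridable in the multipole",
    "parameter file, not values taken from any specific databank."
  ],
  "H": {
    "Z": 1,
    "core": [],
    "valence": [[1, 1.0, 1.0]],
    "deformation": {"n_l": [0, 1, 2], "zeta_bohr": 2.0}
  },
  "C": {
    "Z": 6,
    "core": [[1, 5.6727, 2.0]],
    "valence": [[2, 1.6083, 2.0], [2, 1.5679, 2.0]],
    "deformation": {"n_l": [2, 2, 2, 3, 4], "zeta_bohr": 3.0}
  },
  "N": {
    "Z": 7,
    "core": [[1, 6.6651, 2.0]],
    "valence": [[2, 1.9237, 2.0], [2, 1.9170, 3.0]],
    "deformation": {"n_l": [2, 2, 2, 3, 4], "zeta_bohr": 3.8}
  },
  "O": {
    "Z": 8,
    "core": [[1, 7.6579, 2.0]],
    "valence": [[2, 2.2458, 2.0], [2, 2.2266, 4.0]],
    "deformation": {"n_l": [2, 2, 2, 3, 4], "zeta_bohr": 4.5}
  }
}
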