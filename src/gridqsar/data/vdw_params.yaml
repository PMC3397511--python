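# Lennard-Jones 6-12 parameters per element.
# r_star: minimum-energy radius contribution (Angstrom), combined additively
#         (R_ij = r_star_i + r_star_probe).
# epsilon: well depth (kcal/mol), combined geometrically.
# Values follow the published Tripos-style van der Waals set; swap this file
# to use a different parameterization.
elements:
  H:  {r_star: 1.50, epsilon: 0.042}
  C:  {r_star: 1.70, epsilon: 0.107}
  N:  {r_star: 1.55, epsilon: 0.095}
  O:  {r_star: 1.52, epsilon: 0.116}
  F:  {r_star: 1.47, epsilon: 0.109}
  P:  {r_star: 1.80, epsilon: 0.314}
  S:  {r_star: 1.80, epsilon: 0.314}
  Cl: {r_star: 1.75, epsilon: 0.314}
  Br: {r_star: 1.85, epsilon: 0.434}
  I:  {r_star: 1.98, epsilon: 0.623}
probe:
  r_star: 1.70      # sp3 carbon probe
  epsilon: 0.107
  charge: 1.0       # elementary charge units
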