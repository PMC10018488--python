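# Built-in scorer parameter set, version 1.
#
# All constants of the term-level empirical energy live here so they can be
# tuned without code changes. Energies are arbitrary energy units; distances
# are Angstrom. Pair r_min = radius_i + radius_j; pair well depth
# eps = sqrt(eps_i * eps_j).
version: 1

lj:
  cutoff: 8.0          # pairs beyond this contribute nothing
  repulsion_cap: 10.0  # per-pair cap on the 6-12 repulsive branch
  radius:
    C: 1.90
    N: 1.75
    O: 1.65
    S: 2.00
  epsilon:
    C: 0.10
    N: 0.14
    O: 0.18
    S: 0.18

electrostatics:
  coulomb_constant: 332.0
  dielectric_slope: 4.0   # distance-dependent dielectric eps(r) = slope * r
  cutoff: 8.0
  # Formal charges of the standard charged groups; His neutral, termini neutral.
  charges:
    ASP: {OD1: -0.5, OD2: -0.5}
    GLU: {OE1: -0.5, OE2: -0.5}
    LYS: {NZ: 1.0}
    ARG: {NH1: 0.5, NH2: 0.5}

hbond:
  strength: -1.0  # per fully formed N/O...N/O contact
  r_full: 2.8     # ramp = 1 at or below
  r_zero: 3.5     # ramp = 0 at or beyond

solvation:
  cutoff: 6.0
  # per-atom burial scores summed over interchain contact pairs:
  # carbon/sulfur burial is favorable, uncompensated polar burial penalized
  s:
    C: -0.05
    S: -0.05
    N: 0.08
    O: 0.08

clash:
  slope: 0.8  # e_clash contribution = slope * (r_min - r) for r < r_min

# Residue reference energies (unfolded-state baseline), one per amino acid.
reference_energies:
  A: 0.10
  C: 0.00
  D: -0.30
  E: -0.25
  F: 0.30
  G: 0.35
  H: -0.10
  I: 0.25
  K: -0.20
  L: 0.25
  M: 0.10
  N: -0.25
  P: 0.15
  Q: -0.20
  R: -0.25
  S: -0.05
  T: 0.00
  V: 0.20
  W: 0.25
  Y: 0.10
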