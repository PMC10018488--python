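# Methods

This note documents the models, conventions and design choices behind the
scan pipeline, in the order the pipeline runs them.

## Structure model and parsing policy

The pipeline operates on exactly two chains of a PDB file, in **author
residue numbering** (with insertion codes): reported interface mutations
are conventionally written against author numbers, so that numbering is
the canonical coordinate system everywhere, including mutation codes
(`FB19D`, or `FB19AD` with insertion code A).

Parsing rules, chosen where the format leaves room:

* only MODEL 1 of multi-model (NMR) files, with a recorded warning;
* waters and non-amino-acid HETATM groups (ligands, ions, cofactors) are
  excluded — the scan concerns amino-acid interfaces;
* amino-acid-like HETATM residues (e.g. selenomethionine) are kept with
  one-letter code `X`: they participate in distance calculations and may
  be reported as interfacial, but are never mutated;
* alternate locations: the highest-occupancy conformer wins, ties broken
  by alphabetically first alt-loc identifier — deterministic and
  occupancy-faithful;
* hydrogens are retained as atoms but flagged non-heavy.

Writing uses fixed PDB columns (coordinates at 3 decimals); parse → write
→ parse is the identity on the retained atom set up to that quantization.

## Interface detection

A residue of the analysis chain is interfacial iff the minimum Euclidean
distance from any of its **heavy** atoms to any heavy atom of the partner
chain is **≤ cutoff** (inclusive). Default cutoff 5.0 Å; the CLI restricts
it to 3.0–8.0 Å (the library accepts any positive value with a warning).

Two deliberate conventions:

* *Heavy atoms only.* Deposited structures carry hydrogens
  inconsistently; including them would make the interface definition
  depend on deposition and protonation details rather than geometry.
* *Inclusive boundary.* A residue exactly at the cutoff is interfacial;
  the tie behavior is fixed and tested.

The production implementation uses a k-d tree; its contract is exact set
equality with the all-pairs scan, enforced in the test suite against an
independent brute-force oracle.

## Mutation enumeration

All 19 substitutions at every interfacial standard residue: |mutations| =
19·N always. Ordering is fixed (position, then the amino-acid alphabet
`ACDEFGHIKLMNPQRSTVWY`) so repeated runs give byte-identical lists.
Mutation lists can be emitted in a canonical dialect (one code per line)
or the `;`-terminated per-line dialect consumed by BuildMutant-style
external tools. Multi-point mutations are out of scope.

## Built-in scorer

The built-in scorer is an intentionally simple, fully specified
term-level empirical energy sharing the term *structure* of the empirical
force fields commonly used for interface scanning (van der Waals,
electrostatics, hydrogen bonding, desolvation, per-residue reference
energies, clash penalty). It is **not** a reimplementation of any
licensed force field, and its absolute values are arbitrary energy units;
only comparisons within one landscape are meaningful. Scores from
different backends are never mixed.

Functional forms (all constants in `src/proton_scan/scoring/params.yaml`,
version 1, so they can be tuned without code changes):

| term | form | notes |
|---|---|---|
| e_vdw | ε·((r_min/r)¹² − 2(r_min/r)⁶), pairs ≤ 8 Å | r_min = R_i + R_j, ε = √(ε_i ε_j); per-pair cap +10 |
| e_elec | 332·q_i·q_j / (ε(r)·r), ε(r) = 4r | formal charges: Asp/Glu carboxylate O −0.5, Lys NZ +1.0, Arg NH1/NH2 +0.5; His and termini neutral |
| e_hbond | −1.0·ramp(r) per N/O–N/O pair | ramp 1 at r ≤ 2.8 Å, linear to 0 at r ≥ 3.5 Å; distance-only, no angular term (documented limitation) |
| e_solv | s(t_i) + s(t_j) per contact ≤ 6 Å | s(C) = s(S) = −0.05 (favorable burial), s(N) = s(O) = +0.08 (uncompensated polar burial) |
| e_clash | 0.8·(r_min − r) for r < r_min | linear overlap penalty |
| e_ref | per-residue constant | enters stability only; cancels in binding |

Water-bridge, conformational-entropy and association-rate terms of richer
empirical formulas have no published functional form at this level and
are fixed to zero; the breakdown object documents that mapping.

**Binding** is the sum of pairwise *interchain* terms only: the
separated-partner reference state cancels every intrachain contribution
by construction, so ΔΔG_bind = total(mutant) − total(wild type) needs no
monomer calculation and tends to zero as the partners separate (tested at
100 Å).

**Stability** is a local-environment proxy: intramolecular vdW +
electrostatics + hydrogen bonds + clash between the residue's heavy atoms
and all same-chain heavy atoms within the pair cutoff, excluding 1-2/1-3
peptide-bond neighbours (C–N; CA–N, O–N, C–CA across the bond), plus the
residue-type reference energy. The mutation's stability score is the
mutant-minus-wild-type difference at the mutated position. Whether a
complex-wide or residue-local stability is the better filter input was an
open design choice; the local proxy was selected because it isolates the
mutated position and keeps the 19·N scan O(N) in structure size.

No pre-scoring energy minimization is performed in the built-in path;
strain relief is handled entirely by the rotamer scan. This keeps the
scorer deterministic and dependency-free; external backends are expected
to have run their own repair/minimization before scoring.

## Mutant model building

Backbone atoms (N, CA, C, O, plus backbone hydrogens) are never moved.
The side chain is rebuilt from the ideal internal geometry (bond lengths,
angles, dihedrals) of the CCD component templates, anchored on the actual
local N/CA/C frame, so every chi dihedral is realized exactly with
respect to the real backbone. Each rotatable chi is scanned exhaustively
over {−60°, 60°, 180°} (≤ 3⁴ = 81 combinations; LYS/ARG have four chis),
and the rotamer minimizing e_vdw + e_clash against all surrounding atoms
within the pair cutoff is kept. Ties go to the lexicographically smallest
chi tuple, making the whole construction bit-deterministic. GLY removes
the side chain; ALA places only CB (within 0.05 Å of the ideal
tetrahedral position); PRO keeps its ring at template dihedrals and
records a geometry warning when the local φ is outside [−120°, −30°].
A mutation that cannot be built (missing backbone) is recorded with a
failed status; one unbuildable mutant never aborts a scan.

## Outlier statistics

Quartiles of the pooled ddG landscape (all positions × 19, a single box —
not per position) are computed by **linear interpolation between order
statistics** (numpy `method="linear"`, the common "type 7" rule). This is
the single most result-sensitive convention the box-and-whisker leaves
open, so it is an explicit configuration option with this default.
Whiskers sit at Q1 − k·IQR and Q3 + k·IQR; k defaults to 1.5 and the CLI
restricts it to 1.5–2.5. "Falling outside" is read as **strict**
inequality — a score exactly on a whisker is not an outlier — also
configurable (`strict_boundary`). Failed-status mutations are excluded
from the sample; fewer than 4 finite values is an error advising a larger
interface or cutoff. For normal data at k = 1.5 the expected outlier
(false-positive) rate is ≈ 0.7%, which the tests verify by Monte-Carlo.

## Designer filters

* **Stability rule:** keep a mutation iff its stability score is
  strictly < 0. A score of exactly 0.0 is removed.
* **PSSM rule** (optional): the PSSM is user-supplied, log-odds-like
  (positive = evolutionarily favored), keyed by author position with all
  20 amino-acid columns per covered position. A *depleting* mutation is
  kept iff its score is ≤ 0; an *enriching* mutation iff its score is
  > 0. Note the deliberate asymmetry at zero. Without a PSSM the filter
  is skipped and provenance flags read not-applicable.

Both rules are per-mutation predicates, so their composition is
order-independent (asserted in the tests); they are applied
stability-first by convention. Every outlier appears in the designer
table with explicit pass/fail flags per filter, so nothing silently
disappears.

## Synthetic fixtures

The generator module makes every stage testable without downloads:

* **Toy dimers.** `two-strands`: two flat ideal-geometry backbones with
  chain B translated perpendicular to the backbone plane, so every
  residue's minimum interchain distance equals the requested gap exactly
  and the ground-truth interface is known by construction. `helix-pair`:
  two parallel ideal helices separated along an axis solved (by root
  finding) so the global minimum distance equals the gap, giving a
  partial interface; ground truth comes from an independent all-pairs
  scan. Backbones use fixed ideal bond lengths/angles; no physical
  realism is claimed beyond the distances, and wild-type side chains
  beyond the backbone are not placed.
* **Synthetic landscapes.** Pooled ddG values drawn N(μ, σ) (defaults
  0, 1) with planted (position, amino-acid, value) extremes inserted
  verbatim; stabilities N(0, 1); bit-reproducible under a single integer
  seed, one generator instance per call.

What passing on these fixtures does **not** show: real interfaces have
packed side chains, irregular geometry and correlated per-position score
distributions, none of which the toys emulate. The fixtures validate the
machinery (set logic, statistics, determinism, energetics contracts), not
predictive accuracy on real complexes — the real-structure checks in
`tests/test_acceptance.py` exist for that and require externally supplied
inputs (see README).

## Problem sizes and numerical choices

* Test-suite scans use toy dimers of 3–8 residues per chain (≤ ~70
  atoms) and landscapes of 8–40 positions; the Monte-Carlo rate check
  uses 500 seeded landscapes of 40 positions (760 scores each). The
  acceptance script uses the same scales.
* Distances and energies are float64 throughout; pair distances are
  clamped at 10⁻⁶ Å to avoid division by zero; the LJ repulsive branch is
  capped at +10 per pair so a single overlap cannot dominate a landscape.
* All tie-breaks (alt-loc, rotamer, ordering) are lexicographic and
  documented; two runs of any scan produce byte-identical tables.
* Figures are rendered with the Agg backend and are derived entirely
  from data that is also written as CSV/JSON.

## Known limitations

* The built-in scorer has no angular hydrogen-bond term, no backbone
  flexibility, no explicit solvent, no protonation/pKa model, and its
  magnitudes are not calibrated to kcal/mol; it is a deterministic,
  transparent stand-in with the right term structure, suitable for
  exercising the pipeline and for relative comparisons on one landscape.
* The discrete 3-state chi scan cannot resolve fine rotamer preferences;
  clash relief is rigid-backbone only.
* PSSM generation is out of scope — the matrix is an input, and its
  numbering must match the analysis chain's author numbering (a coverage
  check guards against mismatches).
* No SASA/buried-surface interface definition; the distance criterion is
  the only one implemented.
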