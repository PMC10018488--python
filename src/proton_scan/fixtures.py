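"""Synthetic inputs: toy PDB dimers with known interface geometry and
synthetic ddG landscapes with planted outliers.

These generators make every pipeline stage testable without downloading
real structures. The toy dimers use fixed ideal-ish backbone geometry; no
physical realism is claimed beyond the interchain distances, which are
controlled exactly:

* ``two-strands`` — two flat, parallel extended chains; chain B is chain A
  translated perpendicular to the backbone plane, so *every* residue's
  minimum interchain heavy-atom distance equals the requested gap exactly
  and the ground-truth interface at any cutoff >= gap is the whole
  analysis chain;
* ``helix-pair`` — two parallel ideal helices; after construction chain B
  is shifted along the separation axis so the global minimum interchain
  distance equals the gap, giving a partial interface. The ground-truth
  list is computed by an independent all-pairs distance scan (plain
  loops), not by the production detector.

Landscape generation is bit-reproducible under a fixed seed; planted
(position, amino-acid, value) entries appear verbatim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .aminoacids import AA1_TO_3, ALPHABET
from .mutations import MutationSpec
from .scoring.backends import MutationScore
from .structure_io import AtomRecord, DimerStructure, ResidueRef

__all__ = ["ToyDimerSpec", "LandscapeSpec", "make_toy_dimer",
           "make_synthetic_landscape"]

# flat backbone template (z = 0) with ideal bond lengths and the ideal
# N-CA-C angle (111 deg); x advances by _SPACING per residue
_BB_TEMPLATE = {
    "N": (0.000, 0.000, 0.0),
    "CA": (1.458, 0.000, 0.0),
    "C": (2.005, 1.424, 0.0),
    "O": (1.241, 2.386, 0.0),
}
_SPACING = 3.8


@dataclass(frozen=True)
class ToyDimerSpec:
    """Geometry of a synthetic two-chain complex."""

    n_residues_a: int = 5
    n_residues_b: int = 5
    gap: float = 4.5
    sequence_a: str | None = None  # default poly-Ala
    sequence_b: str | None = None
    geometry: str = "two-strands"  # or "helix-pair"

    def __post_init__(self) -> None:
        if self.gap <= 0:
            raise ValueError("gap must be positive")
        if self.geometry not in ("two-strands", "helix-pair"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        for seq, n in ((self.sequence_a, self.n_residues_a),
                       (self.sequence_b, self.n_residues_b)):
            if seq is not None:
                if len(seq) != n:
                    raise ValueError("sequence length disagrees with n_residues")
                bad = [c for c in seq if c not in ALPHABET]
                if bad:
                    raise ValueError(f"non-standard amino-acid letter(s): {bad}")


def _strand_coords(n: int) -> list[dict[str, np.ndarray]]:
    out = []
    for i in range(n):
        off = np.array([i * _SPACING, 0.0, 0.0])
        out.append({k: np.array(v) + off for k, v in _BB_TEMPLATE.items()})
    return out


def _helix_coords(n: int) -> list[dict[str, np.ndarray]]:
    # parametric ideal alpha helix: 100 deg twist, 1.5 A rise per residue
    out = []
    for i in range(n):
        t = math.radians(100.0 * i)
        res = {}
        for name, (dr, da, dz) in {
            "N": (2.3, -0.45, -0.8), "CA": (2.3, 0.0, 0.0),
            "C": (2.3, 0.38, 0.6), "O": (3.4, 0.38, 0.8),
        }.items():
            r = dr
            ang = t + da
            res[name] = np.array([r * math.cos(ang), r * math.sin(ang),
                                  1.5 * i + dz])
        out.append(res)
    return out


def _build_chain(chain_id: str, seq: str, backbones, with_cb: bool,
                 serial_start: int) -> tuple[list[ResidueRef], dict, int]:
    residues, atoms = [], {}
    serial = serial_start
    for i, (aa1, bb) in enumerate(zip(seq, backbones), start=1):
        ref = ResidueRef(chain_id, i, "", AA1_TO_3[aa1], aa1)
        recs = []
        for name in ("N", "CA", "C", "O"):
            serial += 1
            x, y, z = map(float, bb[name])
            recs.append(AtomRecord(serial, name, name[0], "", x, y, z))
        if with_cb and aa1 != "G" and "CB" in bb:
            serial += 1
            x, y, z = map(float, bb["CB"])
            recs.append(AtomRecord(serial, "CB", "C", "", x, y, z))
        residues.append(ref)
        atoms[ref] = recs
    return residues, atoms, serial


def _min_interchain_distance(atoms_a: list[np.ndarray],
                             atoms_b: list[np.ndarray]) -> float:
    best = math.inf
    for pa in atoms_a:
        for pb in atoms_b:
            best = min(best, float(np.linalg.norm(pa - pb)))
    return best


def make_toy_dimer(spec: ToyDimerSpec) -> tuple[DimerStructure, list[ResidueRef]]:
    """Build a synthetic dimer; returns (structure, ground-truth interface).

    The ground truth is the list of chain-B residues within ``spec.gap`` of
    chain A — i.e. the interface of the analysis chain B at any cutoff in
    [gap, gap + margin) — computed independently of the production
    detector.
    """
    seq_a = spec.sequence_a or "A" * spec.n_residues_a
    seq_b = spec.sequence_b or "A" * spec.n_residues_b

    if spec.geometry == "two-strands":
        bb_a = _strand_coords(spec.n_residues_a)
        bb_b = _strand_coords(spec.n_residues_b)
        shift = np.array([0.0, 0.0, spec.gap])
        bb_b = [{k: v + shift for k, v in r.items()} for r in bb_b]
    else:
        bb_a = _helix_coords(spec.n_residues_a)
        bb_b = _helix_coords(spec.n_residues_b)
        flat_a = [p for r in bb_a for p in r.values()]
        flat_b0 = [p for r in bb_b for p in r.values()]

        # place the second helix axis-parallel at the x offset that makes the
        # global minimum interchain distance equal the requested gap
        def min_dist_at(dx: float) -> float:
            off = np.array([dx, 0.0, 0.0])
            return _min_interchain_distance(flat_a, [p + off for p in flat_b0])

        from scipy.optimize import brentq
        dx = float(brentq(lambda d: min_dist_at(d) - spec.gap, 0.1, 60.0,
                          xtol=1e-10)) - 1e-7  # land just inside the gap
        bb_b = [{k: v + np.array([dx, 0.0, 0.0]) for k, v in r.items()}
                for r in bb_b]

    res_a, atoms_a, serial = _build_chain("A", seq_a, bb_a, False, 0)
    res_b, atoms_b, _ = _build_chain("B", seq_b, bb_b, False, serial)
    structure = DimerStructure("A", "B", res_a + res_b, {**atoms_a, **atoms_b})

    flat_a = [np.array(a.coord) for r in res_a for a in structure.atoms[r]]
    truth = []
    for r in res_b:
        pts = [np.array(a.coord) for a in structure.atoms[r]]
        if _min_interchain_distance(pts, flat_a) <= spec.gap + 1e-9:
            truth.append(r)
    return structure, truth


@dataclass(frozen=True)
class LandscapeSpec:
    """A synthetic pooled ddG landscape: normal baseline + planted outliers."""

    n_positions: int = 10
    mu: float = 0.0
    sigma: float = 1.0
    planted: tuple = ()  # ((seq_num, mut_aa1, ddg_value), ...)
    seed: int = 0
    chain_id: str = "B"

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        for pos, aa, _ in self.planted:
            if not 1 <= pos <= self.n_positions:
                raise ValueError(f"planted position {pos} outside 1..{self.n_positions}")
            if aa not in ALPHABET:
                raise ValueError(f"planted amino acid {aa!r} not standard")


def make_synthetic_landscape(spec: LandscapeSpec) -> list[MutationScore]:
    """Seeded, reproducible scores over ``n_positions`` x 19 mutations.

    Wild types cycle through the amino-acid alphabet by position; baseline
    ddG values are N(mu, sigma) draws, stabilities are N(0, 1) draws from
    the same generator, and planted (position, aa, value) entries replace
    the baseline ddG verbatim.
    """
    rng = np.random.default_rng(spec.seed)
    planted = {(pos, aa): val for pos, aa, val in spec.planted}
    for (pos, aa), _ in planted.items():
        wt = ALPHABET[(pos - 1) % 20]
        if aa == wt:
            raise ValueError(f"planted mutation at {pos} equals the wild type {wt}")
    scores = []
    for pos in range(1, spec.n_positions + 1):
        wt = ALPHABET[(pos - 1) % 20]
        for aa in ALPHABET:
            if aa == wt:
                continue
            ddg = float(rng.normal(spec.mu, spec.sigma))
            stability = float(rng.normal(0.0, 1.0))
            if (pos, aa) in planted:
                ddg = float(planted[(pos, aa)])
            scores.append(MutationScore(
                mutation=MutationSpec(spec.chain_id, pos, "", wt, aa),
                ddg_bind=ddg,
                stability=stability,
                backend="synthetic",
            ))
    return scores
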