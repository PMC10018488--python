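"""Deterministic mutant model building with a discrete rotamer scan.

The backbone (N, CA, C, O and any backbone hydrogens) of the mutated
position is left untouched; the side chain is rebuilt from the target
residue's ideal internal geometry (bond lengths, angles and dihedrals of
the CCD component templates, via biotite) anchored on the actual local
N/CA/C frame, so every chi dihedral is realized exactly with respect to
the real backbone. Each rotatable chi is scanned exhaustively over the
discrete set {-60, 60, 180} degrees (at most 3^4 = 81 combinations) and
the rotamer minimizing the vdW + clash energy against all surrounding
atoms within the pair cutoff is kept. Ties go to the lexicographically
smallest chi tuple, so the whole construction is fully deterministic.
GLY removes the side chain entirely; ALA places only CB; PRO keeps its
ring at template dihedrals (no free chi in this scheme) and a
backbone-geometry warning is recorded when the local phi angle is hostile
to a proline.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

import numpy as np

from ..aminoacids import AA1_TO_3
from ..errors import ModelError
from ..mutations import MutationSpec
from ..structure_io import AtomRecord, DimerStructure, ResidueRef
from .energy import sidechain_environment_energy
from .params import ScoringParams, default_params

__all__ = ["build_mutant_model", "rotamer_candidates", "CHI_ATOMS", "CHI_ANGLES"]

CHI_ANGLES = (-60.0, 60.0, 180.0)

# Standard chi dihedral definitions (atom-name quadruples), heavy atoms only.
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "ALA": [],
    "GLY": [],
}

_BACKBONE = ("N", "CA", "C", "O")
_BACKBONE_H = {"H", "H1", "H2", "H3", "HA", "HA2", "HA3"}


def _dihedral(p0, p1, p2, p3) -> float:
    """Dihedral angle in degrees, IUPAC sign convention."""
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return math.degrees(math.atan2(y, x))


def _angle(p0, p1, p2) -> float:
    """Bond angle p0-p1-p2 in degrees."""
    u = p0 - p1
    v = p2 - p1
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def _nerf(gg, g, p, bond, angle_deg, dihedral_deg) -> np.ndarray:
    """Place an atom from three anchors and internal coordinates
    (natural-extension reference frame)."""
    theta = math.radians(angle_deg)
    phi = math.radians(dihedral_deg)
    bc = p - g
    bc /= np.linalg.norm(bc)
    n = np.cross(g - gg, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([
        -bond * math.cos(theta),
        -bond * math.sin(theta) * math.cos(phi),
        -bond * math.sin(theta) * math.sin(phi),
    ])
    return p + d[0] * bc + d[1] * m + d[2] * n


@lru_cache(maxsize=None)
def _sidechain_recipe(aa3: str):
    """Internal-coordinate build recipe for a residue's heavy side chain.

    Returns an ordered list of
    ``(name, element, parent, grandparent, greatgrand, bond, angle, dihedral)``
    measured on the CCD ideal-coordinate template. The anchor chain is
    CA -> N -> C, so the first entry places CB from the real backbone frame.
    """
    import biotite.structure.info as info

    arr = info.residue(aa3)
    heavy = (arr.element != "H") & (arr.atom_name != "OXT")
    idx = np.where(heavy)[0]
    names = [str(n) for n in arr.atom_name[idx]]
    coords = {n: np.array(c, dtype=float)
              for n, c in zip(names, arr.coord[idx])}
    elements = dict(zip(names, (str(e) for e in arr.element[idx])))
    remap = {int(old): new for new, old in enumerate(idx)}
    adj: dict[str, set[str]] = {n: set() for n in names}
    for i, j, _ in arr.bonds.as_array():
        if int(i) in remap and int(j) in remap:
            a, b = names[remap[int(i)]], names[remap[int(j)]]
            adj[a].add(b)
            adj[b].add(a)

    # BFS into the side chain from CA; anchors continue CA -> N -> C
    parent = {"CA": "N", "N": "C"}
    order: list[str] = []
    queue = ["CA"]
    seen = {"N", "C", "O", "CA"}
    while queue:
        cur = queue.pop(0)
        for nbr in sorted(adj[cur], key=names.index):
            if nbr in seen:
                continue
            seen.add(nbr)
            parent[nbr] = cur
            order.append(nbr)
            queue.append(nbr)

    recipe = []
    for name in order:
        p = parent[name]
        g = parent[p]
        gg = parent[g]
        recipe.append((
            name, elements[name], p, g, gg,
            float(np.linalg.norm(coords[name] - coords[p])),
            _angle(coords[name], coords[p], coords[g]),
            _dihedral(coords[name], coords[p], coords[g], coords[gg]),
        ))
    return tuple(recipe)


def _place_sidechain(backbone: dict[str, np.ndarray], aa3: str,
                     chi_values: tuple[float, ...]) -> dict[str, np.ndarray]:
    """Rebuild the side chain on a real backbone frame with given chi values.

    Every atom keeps the template's internal geometry; atoms rotating about
    a chi bond are offset together so siblings (e.g. both CD atoms of LEU)
    follow the set dihedral rigidly.
    """
    recipe = _sidechain_recipe(aa3)
    chis = CHI_ATOMS[aa3]
    template_chi = {}
    for (a_, b_, c_, d_) in chis:
        for (name, _, p, g, gg, _, _, dihedral) in recipe:
            if name == d_ and (p, g, gg) == (c_, b_, a_):
                template_chi[(b_, c_)] = dihedral
    offsets = {}
    for (quad, target) in zip(chis, chi_values):
        _, b_, c_, _ = quad
        offsets[(b_, c_)] = target - template_chi[(b_, c_)]

    coords = dict(backbone)
    for (name, _, p, g, gg, bond, angle, dihedral) in recipe:
        dihedral += offsets.get((g, p), 0.0)
        coords[name] = _nerf(coords[gg], coords[g], coords[p], bond, angle, dihedral)
    return coords


def _phi(structure: DimerStructure, res: ResidueRef) -> float | None:
    chain = structure.chain_residues(res.chain_id)
    i = chain.index(res)
    if i == 0:
        return None
    coords = {}
    for name in ("N", "CA", "C"):
        for a in structure.atoms[res]:
            if a.name == name:
                coords[name] = np.array(a.coord)
    prev_c = None
    for a in structure.atoms[chain[i - 1]]:
        if a.name == "C":
            prev_c = np.array(a.coord)
    if prev_c is None or len(coords) < 3:
        return None
    return _dihedral(prev_c, coords["N"], coords["CA"], coords["C"])


def rotamer_candidates(structure: DimerStructure, spec: MutationSpec
                       ) -> list[tuple[tuple, list[AtomRecord]]]:
    """Every discrete rotamer of the mutant side chain, with placed atoms.

    Exposes the exact candidate set the builder chooses from, so the
    selected rotamer can be validated against an independent energy
    recomputation. GLY/ALA/PRO have no rotatable chi and return the single
    templated placement (empty for GLY).
    """
    res = structure.find_residue(spec.chain_id, spec.seq_num, spec.insertion_code)
    mut3 = AA1_TO_3[spec.mut_aa1]
    if mut3 == "GLY":
        return [((), [])]
    backbone = {a.name: np.array(a.coord)
                for a in structure.atoms[res]
                if a.is_heavy and a.name in _BACKBONE}
    missing = [n for n in ("N", "CA", "C") if n not in backbone]
    if missing:
        raise ModelError(
            f"residue {res.chain_id}/{res.label} missing backbone atoms: "
            + ",".join(missing))
    recipe = _sidechain_recipe(mut3)
    element_of = {name: elem for (name, elem, *_rest) in recipe}
    side_names = [name for (name, *_rest) in recipe]
    chis = CHI_ATOMS[mut3]

    def records(coords):
        return [AtomRecord(0, n, element_of[n].upper(), "",
                           *map(float, coords[n])) for n in side_names]

    combos = ([()] if not chis else
              list(itertools.product(CHI_ANGLES, repeat=len(chis))))
    out = []
    for combo in combos:
        coords = _place_sidechain(backbone, mut3, combo)
        out.append((combo, records(coords)))
    return out


def build_mutant_model(structure: DimerStructure, spec: MutationSpec,
                       params: ScoringParams | None = None) -> DimerStructure:
    """Return a new structure with one residue mutated (backbone fixed).

    Raises :class:`ModelError` when the residue is absent, disagrees with
    the spec's wild type, or lacks backbone atoms.
    """
    p = params or default_params()
    try:
        res = structure.find_residue(spec.chain_id, spec.seq_num, spec.insertion_code)
    except KeyError as exc:
        raise ModelError(str(exc)) from exc
    if res.aa1 != spec.wt_aa1:
        raise ModelError(
            f"wild type mismatch at {spec.chain_id}/{spec.seq_num}: "
            f"structure has {res.aa1}, spec says {spec.wt_aa1}"
        )

    old_atoms = structure.atoms[res]
    bb_names = {a.name for a in old_atoms if a.is_heavy and a.name in _BACKBONE}
    missing = [n for n in _BACKBONE if n not in bb_names]
    if missing:
        raise ModelError(
            f"residue {res.chain_id}/{res.label} missing backbone atoms: "
            + ",".join(missing))

    mut3 = AA1_TO_3[spec.mut_aa1]
    kept = [a for a in old_atoms
            if (a.is_heavy and a.name in _BACKBONE)
            or (not a.is_heavy and a.name in _BACKBONE_H)]
    if mut3 == "PRO":
        kept = [a for a in kept if a.name != "H"]  # proline N carries no amide H

    warnings = list(structure.warnings)
    new_ref = ResidueRef(res.chain_id, res.seq_num, res.insertion_code,
                         mut3, spec.mut_aa1)

    side_atoms: list[AtomRecord] = []
    if mut3 != "GLY":
        candidates = rotamer_candidates(structure, spec)
        if len(candidates) == 1:
            side_atoms = candidates[0][1]
        else:
            environment = [
                (r, a)
                for r in structure.residues if r != res
                for a in structure.atoms[r] if a.is_heavy
            ]
            best = None
            for combo, side in candidates:
                energy = sidechain_environment_energy(
                    [(new_ref, a) for a in side], environment, p)
                if best is None or energy < best[0]:
                    best = (energy, combo, side)
            side_atoms = best[2]

    if mut3 == "PRO":
        phi = _phi(structure, res)
        if phi is not None and not (-120.0 <= phi <= -30.0):
            warnings.append(
                f"mutation {spec.code}: backbone phi {phi:.0f} deg is strained "
                "for proline")

    new_structure = structure.replace_residue(res, new_ref, kept + side_atoms)
    new_structure.warnings = warnings
    return _renumber(new_structure)


def _renumber(structure: DimerStructure) -> DimerStructure:
    """Assign sequential atom serials in write order (deterministic output)."""
    from dataclasses import replace

    serial = 0
    new_atoms = {}
    for chain_id in (structure.chain_a_id, structure.chain_b_id):
        for res in structure.chain_residues(chain_id):
            updated = []
            for a in structure.atoms[res]:
                serial += 1
                updated.append(replace(a, serial=serial))
            new_atoms[res] = updated
    return DimerStructure(structure.chain_a_id, structure.chain_b_id,
                          list(structure.residues), new_atoms,
                          list(structure.warnings))
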