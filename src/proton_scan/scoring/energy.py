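"""Term-level empirical energy of a two-chain complex.

This is an intentionally simple, fully specified scorer sharing the *term
structure* of the empirical force fields used for interface scanning
(van der Waals, electrostatics, hydrogen bonding, desolvation, reference
energies, clash penalty), not a reimplementation of any licensed force
field. Water-bridge, backbone/side-chain entropy and association-rate terms
of richer formulas have no published functional form at this level and are
fixed to zero here.

Binding is evaluated as the sum of pairwise *interchain* terms only: the
separated-partner reference state cancels all intrachain contributions by
construction, so no explicit monomer calculation is needed.

Functional forms (constants in ``params.yaml``):

* ``e_vdw``   — Lennard-Jones 6-12 over heavy-atom pairs within 8 A,
  ``eps*((rm/r)^12 - 2 (rm/r)^6)``, capped at +10 per pair;
* ``e_elec``  — Coulomb ``332 q_i q_j / (eps(r) r)`` with the
  distance-dependent dielectric ``eps(r) = 4 r``;
* ``e_hbond`` — ``-1.0 * ramp(r)`` per N/O polar pair, ramp linear from 1
  at r <= 2.8 A to 0 at r >= 3.5 A (distance-only, no angular term);
* ``e_solv``  — per contact pair within 6 A, ``s(type_i) + s(type_j)``
  with favorable carbon burial and penalized polar burial;
* ``e_clash`` — ``0.8 (r_min - r)`` for pairs closer than ``r_min``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from ..structure_io import AtomRecord, DimerStructure, ResidueRef
from .params import ScoringParams, default_params

__all__ = ["EnergyBreakdown", "binding_energy", "stability_score"]

_POLAR = ("N", "O")


@dataclass(frozen=True)
class EnergyBreakdown:
    """Per-term energies in arbitrary energy units; total = vdw+elec+hbond+solv-ref+clash."""

    e_vdw: float
    e_elec: float
    e_hbond: float
    e_solv: float
    e_ref: float
    e_clash: float
    total: float

    @classmethod
    def from_terms(cls, e_vdw=0.0, e_elec=0.0, e_hbond=0.0, e_solv=0.0,
                   e_ref=0.0, e_clash=0.0) -> "EnergyBreakdown":
        total = e_vdw + e_elec + e_hbond + e_solv - e_ref + e_clash
        return cls(e_vdw, e_elec, e_hbond, e_solv, e_ref, e_clash, total)


def _element_type(element: str) -> str:
    """Collapse heavy elements onto the parameterized C/N/O/S types."""
    if element in ("C", "N", "O", "S"):
        return element
    if element == "SE":
        return "S"
    return "C"


def _arrays(pairs: list[tuple[ResidueRef, AtomRecord]], p: ScoringParams):
    coords = np.array([a.coord for _, a in pairs], dtype=float).reshape(-1, 3)
    types = [_element_type(a.element) for _, a in pairs]
    radius = np.array([p.lj_radius[t] for t in types])
    eps = np.array([p.lj_epsilon[t] for t in types])
    charge = np.array([p.charge_of(res.aa3, a.name) for res, a in pairs])
    polar = np.array([t in _POLAR for t in types])
    solv = np.array([p.solv_s[t] for t in types])
    return coords, radius, eps, charge, polar, solv


def _pair_terms(set1, set2, p: ScoringParams, exclude=None, with_solv=True):
    """Summed pair terms between two heavy-atom sets.

    ``exclude`` is an optional boolean (n1, n2) mask of pairs to omit
    (bonded 1-2/1-3 neighbours in the stability context).
    """
    c1, r1, e1, q1, pol1, s1 = _arrays(set1, p)
    c2, r2, e2, q2, pol2, s2 = _arrays(set2, p)
    if len(c1) == 0 or len(c2) == 0:
        return EnergyBreakdown.from_terms()
    d = cdist(c1, c2)
    if exclude is not None:
        d = np.where(exclude, np.inf, d)
    d = np.maximum(d, 1e-6)

    rmin = r1[:, None] + r2[None, :]
    within = d <= p.lj_cutoff
    ratio = np.where(within, rmin / d, 0.0)
    eps = np.sqrt(e1[:, None] * e2[None, :])
    lj = eps * (ratio ** 12 - 2.0 * ratio ** 6)
    e_vdw = float(np.minimum(lj, p.lj_cap)[within].sum())

    qq = q1[:, None] * q2[None, :]
    em = (qq != 0.0) & (d <= p.elec_cutoff)
    e_elec = float((p.coulomb_constant * qq[em] / (p.dielectric_slope * d[em] ** 2)).sum())

    hm = pol1[:, None] & pol2[None, :] & (d < p.hb_r_zero)
    ramp = np.clip((p.hb_r_zero - d) / (p.hb_r_zero - p.hb_r_full), 0.0, 1.0)
    e_hbond = float(p.hb_strength * ramp[hm].sum())

    e_solv = 0.0
    if with_solv:
        sm = d <= p.solv_cutoff
        e_solv = float((s1[:, None] + s2[None, :])[sm].sum())

    cm = d < rmin
    e_clash = float((p.clash_slope * (rmin - d))[cm].sum())

    return EnergyBreakdown.from_terms(e_vdw=e_vdw, e_elec=e_elec, e_hbond=e_hbond,
                                      e_solv=e_solv, e_clash=e_clash)


def binding_energy(structure: DimerStructure, params: ScoringParams | None = None) -> EnergyBreakdown:
    """Interchain binding energy of the complex (arbitrary energy units).

    Reference energies cancel between bound and separated states, so
    ``e_ref`` is zero here; the total tends to zero as the partners are
    pulled apart.
    """
    p = params or default_params()
    set_a = structure.heavy_atoms(structure.chain_a_id)
    set_b = structure.heavy_atoms(structure.chain_b_id)
    return _pair_terms(set_a, set_b, p, with_solv=True)


# 1-2 / 1-3 atom-name pairs across a peptide bond, (previous residue, this residue)
_PEPTIDE_EXCLUDE_PREV = {("C", "N"), ("CA", "N"), ("O", "N"), ("C", "CA")}


def stability_score(structure: DimerStructure, residue: ResidueRef,
                    params: ScoringParams | None = None) -> float:
    """Local folding-stability proxy of one residue.

    Sum of intramolecular vdW, electrostatic, hydrogen-bond and clash terms
    between the residue's heavy atoms and all other same-chain heavy atoms
    within the pair cutoff (1-2/1-3 peptide-bond neighbours excluded), plus
    the residue-type reference energy. A more negative value means a better
    packed, more stabilizing environment.
    """
    p = params or default_params()
    chain = structure.chain_residues(residue.chain_id)
    try:
        pos = chain.index(residue)
    except ValueError:
        raise KeyError(f"residue {residue.label} not in chain {residue.chain_id}")

    self_set = [(residue, a) for a in structure.atoms[residue] if a.is_heavy]
    env_set: list[tuple[ResidueRef, AtomRecord]] = []
    env_role: list[int] = []  # -1 previous neighbour, +1 next neighbour, 0 other
    for j, other in enumerate(chain):
        if other == residue:
            continue
        role = -1 if j == pos - 1 else (+1 if j == pos + 1 else 0)
        for a in structure.atoms[other]:
            if a.is_heavy:
                env_set.append((other, a))
                env_role.append(role)

    if not env_set:
        return p.e_ref(residue.aa1)

    exclude = np.zeros((len(self_set), len(env_set)), dtype=bool)
    for i, (_, sa) in enumerate(self_set):
        for j, (_, ea) in enumerate(env_set):
            if env_role[j] == -1 and (ea.name, sa.name) in _PEPTIDE_EXCLUDE_PREV:
                exclude[i, j] = True
            elif env_role[j] == +1 and (sa.name, ea.name) in _PEPTIDE_EXCLUDE_PREV:
                exclude[i, j] = True

    terms = _pair_terms(self_set, env_set, p, exclude=exclude, with_solv=False)
    return terms.e_vdw + terms.e_elec + terms.e_hbond + terms.e_clash + p.e_ref(residue.aa1)


def sidechain_environment_energy(sidechain: list[tuple[ResidueRef, AtomRecord]],
                                 environment: list[tuple[ResidueRef, AtomRecord]],
                                 params: ScoringParams | None = None) -> float:
    """vdW + clash of a candidate side-chain placement against its surroundings.

    Used by the rotamer scan; the environment is every heavy atom of the
    structure except the residue being rebuilt.
    """
    p = params or default_params()
    terms = _pair_terms(sidechain, environment, p, with_solv=False)
    return terms.e_vdw + terms.e_clash
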