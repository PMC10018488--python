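import math
from dataclasses import replace

import numpy as np
import pytest

from proton_scan import ToyDimerSpec, binding_energy, make_toy_dimer, stability_score
from proton_scan.scoring import default_params
from proton_scan.structure_io import AtomRecord, DimerStructure, ResidueRef

from _oracles import load_raw_params, pair_terms


def _atom(serial, name, x, y, z, element=None):
    return AtomRecord(serial, name, element or name[0], "", x, y, z)


def _two_atom_dimer(name_a, res_a, name_b, res_b, distance, element_a=None, element_b=None):
    from proton_scan.aminoacids import one_letter

    ra = ResidueRef("A", 1, "", res_a, one_letter(res_a))
    rb = ResidueRef("B", 1, "", res_b, one_letter(res_b))
    return DimerStructure("A", "B", [ra, rb], {
        ra: [_atom(1, name_a, 0, 0, 0, element_a)],
        rb: [_atom(2, name_b, distance, 0, 0, element_b)],
    })


def test_lj_well_depth_at_rmin():
    p = default_params()
    rmin = 2 * p.lj_radius["C"]
    s = _two_atom_dimer("CA", "GLY", "CA", "GLY", rmin)
    bd = binding_energy(s)
    assert bd.e_vdw == pytest.approx(-p.lj_epsilon["C"], abs=1e-12)
    assert bd.e_elec == 0.0
    assert bd.e_clash == 0.0


def test_coulomb_closed_form_salt_bridge():
    s = _two_atom_dimer("NZ", "LYS", "OD1", "ASP", 5.0, "N", "O")
    bd = binding_energy(s)
    assert bd.e_elec == pytest.approx(332 * (1.0 * -0.5) / (4.0 * 5.0 * 5.0), abs=1e-12)
    assert bd.e_elec == pytest.approx(-1.66, abs=1e-12)


def test_hbond_ramp_endpoints():
    full = binding_energy(_two_atom_dimer("N", "GLY", "O", "GLY", 2.8))
    gone = binding_energy(_two_atom_dimer("N", "GLY", "O", "GLY", 3.5))
    halfway = binding_energy(_two_atom_dimer("N", "GLY", "O", "GLY", 3.15))
    assert full.e_hbond == pytest.approx(-1.0)
    assert gone.e_hbond == 0.0
    assert halfway.e_hbond == pytest.approx(-0.5)


def test_binding_vanishes_at_large_separation():
    s, _ = make_toy_dimer(ToyDimerSpec(5, 5, 100.0, "LFAKE", "WYRGH"))
    bd = binding_energy(s)
    assert bd.total == 0.0
    assert (bd.e_vdw, bd.e_elec, bd.e_hbond, bd.e_solv, bd.e_clash) == (0,) * 5


def test_breakdown_total_identity(toy_dimer):
    s, _ = toy_dimer
    bd = binding_energy(s)
    recomputed = bd.e_vdw + bd.e_elec + bd.e_hbond + bd.e_solv - bd.e_ref + bd.e_clash
    assert bd.total == pytest.approx(recomputed, abs=1e-9)


def test_binding_rigid_body_invariance(toy_dimer):
    from scipy.spatial.transform import Rotation

    s, _ = toy_dimer
    rot = Rotation.from_euler("zyx", [17.0, 65.0, -40.0], degrees=True)
    shift = np.array([3.0, -7.0, 2.0])
    atoms = {res: [replace(a, **dict(zip("xyz", rot.apply(np.array(a.coord)) + shift)))
                   for a in s.atoms[res]]
             for res in s.residues}
    moved = DimerStructure("A", "B", list(s.residues), atoms)
    b0, b1 = binding_energy(s), binding_energy(moved)
    assert b1.total == pytest.approx(b0.total, abs=1e-6)
    assert b1.e_vdw == pytest.approx(b0.e_vdw, abs=1e-6)


def test_binding_matches_loop_oracle(toy_dimer):
    s, _ = toy_dimer
    set_a = [(r.aa3, a) for r, a in s.heavy_atoms("A")]
    set_b = [(r.aa3, a) for r, a in s.heavy_atoms("B")]
    expect = pair_terms(set_a, set_b)
    bd = binding_energy(s)
    for term, value in expect.items():
        assert getattr(bd, term) == pytest.approx(value, abs=1e-9), term


def test_stability_of_isolated_residue_is_reference_energy():
    p = default_params()
    ra = ResidueRef("A", 1, "", "GLY", "G")
    rb = ResidueRef("B", 1, "", "GLY", "G")
    s = DimerStructure("A", "B", [ra, rb], {
        ra: [_atom(1, "CA", 0, 0, 0)],
        rb: [_atom(2, "CA", 100, 0, 0)],
    })
    assert stability_score(s, ra) == pytest.approx(p.e_ref("G"), abs=1e-12)


def test_engineered_clash_gives_positive_stability():
    ra1 = ResidueRef("A", 1, "", "GLY", "G")
    ra2 = ResidueRef("A", 5, "", "GLY", "G")  # not sequence-adjacent
    rb = ResidueRef("B", 1, "", "GLY", "G")
    s = DimerStructure("A", "B", [ra1, ra2, rb], {
        ra1: [_atom(1, "CA", 0, 0, 0)],
        ra2: [_atom(2, "CA", 1.0, 0, 0)],
        rb: [_atom(3, "CA", 100, 0, 0)],
    })
    assert stability_score(s, ra1) > 0


def test_stability_matches_loop_oracle(toy_dimer):
    """Full scan over a toy chain against an independent pair-sum with the
    same 1-2/1-3 peptide-bond exclusions."""
    s, _ = toy_dimer
    raw = load_raw_params()
    excluded_prev = {("C", "N"), ("CA", "N"), ("O", "N"), ("C", "CA")}
    for chain in ("A", "B"):
        residues = s.chain_residues(chain)
        for pos, res in enumerate(residues):
            self_atoms = [(res.aa3, a) for a in s.atoms[res] if a.is_heavy]
            env, roles = [], []
            for j, other in enumerate(residues):
                if other == res:
                    continue
                for a in s.atoms[other]:
                    if a.is_heavy:
                        env.append((other.aa3, a))
                        roles.append(-1 if j == pos - 1 else (1 if j == pos + 1 else 0))
            exclude = set()
            for i, (_, sa) in enumerate(self_atoms):
                for j, (_, ea) in enumerate(env):
                    if roles[j] == -1 and (ea.name, sa.name) in excluded_prev:
                        exclude.add((i, j))
                    if roles[j] == 1 and (sa.name, ea.name) in excluded_prev:
                        exclude.add((i, j))
            terms = pair_terms(self_atoms, env, raw, exclude=exclude, with_solv=False)
            expected = (terms["e_vdw"] + terms["e_elec"] + terms["e_hbond"]
                        + terms["e_clash"] + raw["reference_energies"][res.aa1])
            assert stability_score(s, res) == pytest.approx(expected, abs=1e-9)


def test_repulsion_capped_per_pair():
    p = default_params()
    s = _two_atom_dimer("CA", "GLY", "CA", "GLY", 0.5)
    bd = binding_energy(s)
    assert bd.e_vdw == pytest.approx(p.lj_cap)
    assert bd.e_clash == pytest.approx(p.clash_slope * (2 * p.lj_radius["C"] - 0.5))
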