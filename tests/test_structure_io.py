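import pytest

from proton_scan import ToyDimerSpec, make_toy_dimer, parse_pdb, write_pdb
from proton_scan.errors import MissingChainError, PdbFormatError
from proton_scan.structure_io import structures_close

from conftest import atom_line, gly_residue


def test_parse_counts_residues_and_chains(mini_dimer_pdb):
    s = parse_pdb(mini_dimer_pdb, "A", "B")
    assert len(s.residues) == 3
    assert {r.chain_id for r in s.residues} == {"A", "B"}
    assert all(r.aa1 == "G" for r in s.residues)


def test_alt_loc_highest_occupancy_wins():
    lines = gly_residue(1, "A", 1) + [
        atom_line(5, "N", "SER", "B", 1, 0, 0, 4.5),
        atom_line(6, "CA", "SER", "B", 1, 1.0, 0, 4.5, occ=0.6, alt="A"),
        atom_line(7, "CA", "SER", "B", 1, 1.5, 0, 4.5, occ=0.4, alt="B"),
        atom_line(8, "C", "SER", "B", 1, 2.4, 0, 4.5),
        atom_line(9, "O", "SER", "B", 1, 2.4, 1.2, 4.5),
    ]
    s = parse_pdb("\n".join(lines), "A", "B")
    ser = s.chain_residues("B")[0]
    cas = [a for a in s.atoms[ser] if a.name == "CA"]
    assert len(cas) == 1
    assert cas[0].alt_loc == "A" and cas[0].x == pytest.approx(1.0)


def test_alt_loc_tie_broken_alphabetically():
    lines = gly_residue(1, "A", 1) + [
        atom_line(5, "N", "SER", "B", 1, 0, 0, 4.5),
        atom_line(6, "CA", "SER", "B", 1, 1.5, 0, 4.5, occ=0.5, alt="B"),
        atom_line(7, "CA", "SER", "B", 1, 1.0, 0, 4.5, occ=0.5, alt="A"),
        atom_line(8, "C", "SER", "B", 1, 2.4, 0, 4.5),
        atom_line(9, "O", "SER", "B", 1, 2.4, 1.2, 4.5),
    ]
    s = parse_pdb("\n".join(lines), "A", "B")
    ca = [a for a in s.atoms[s.chain_residues("B")[0]] if a.name == "CA"][0]
    assert ca.alt_loc == "A"


def test_water_and_ligand_excluded(mini_dimer_pdb):
    extra = [
        atom_line(50, "O", "HOH", "A", 90, 9, 9, 9, record="HETATM"),
        atom_line(51, "FE", "HEM", "B", 91, 8, 8, 8, element="FE", record="HETATM"),
    ]
    s = parse_pdb(mini_dimer_pdb.replace("END", "\n".join(extra) + "\nEND"), "A", "B")
    assert len(s.residues) == 3
    assert all(r.aa3 not in ("HOH", "HEM") for r in s.residues)


def test_selenomethionine_kept_as_nonstandard(mini_dimer_pdb):
    mse = [
        atom_line(60, "N", "MSE", "A", 5, 10, 0.8, 0, record="HETATM"),
        atom_line(61, "CA", "MSE", "A", 5, 11.2, 0, 0, record="HETATM"),
        atom_line(62, "C", "MSE", "A", 5, 12.4, 0.45, 0, record="HETATM"),
        atom_line(63, "O", "MSE", "A", 5, 12.7, 1.6, 0, record="HETATM"),
        atom_line(64, "SE", "MSE", "A", 5, 11.2, -1.8, 0, element="SE", record="HETATM"),
    ]
    s = parse_pdb(mini_dimer_pdb.replace("END", "\n".join(mse) + "\nEND"), "A", "B")
    mse_res = [r for r in s.residues if r.aa3 == "MSE"]
    assert len(mse_res) == 1 and mse_res[0].aa1 == "X"


def test_missing_chain_error_lists_available(mini_dimer_pdb):
    with pytest.raises(MissingChainError) as err:
        parse_pdb(mini_dimer_pdb, "A", "C")
    assert "C" in str(err.value) and "A" in str(err.value) and "B" in str(err.value)


def test_identical_chain_ids_rejected(mini_dimer_pdb):
    with pytest.raises(ValueError):
        parse_pdb(mini_dimer_pdb, "A", "A")


def test_no_amino_acid_records_is_format_error():
    water_only = atom_line(1, "O", "HOH", "A", 1, 0, 0, 0, record="HETATM")
    with pytest.raises(PdbFormatError):
        parse_pdb(water_only + "\nEND\n", "A", "B")
    with pytest.raises(PdbFormatError):
        parse_pdb("REMARK nothing here\nEND\n", "A", "B")


def test_multi_model_uses_first_and_warns(mini_dimer_pdb):
    body = mini_dimer_pdb.replace("END", "").strip()
    shifted = body.replace("   0.000", "   9.000")
    text = f"MODEL     1\n{body}\nENDMDL\nMODEL     2\n{shifted}\nENDMDL\nEND\n"
    s = parse_pdb(text, "A", "B")
    assert any("model 1" in w for w in s.warnings)
    n_atom = s.atoms[s.residues[0]][0]
    assert n_atom.x == pytest.approx(0.0)


@pytest.mark.parametrize("geometry", ["two-strands", "helix-pair"])
def test_round_trip_is_identity(geometry):
    s, _ = make_toy_dimer(ToyDimerSpec(5, 4, 4.5, "LFAKE", "WYRG", geometry))
    once = parse_pdb(write_pdb(s), "A", "B")
    assert structures_close(s, once, coord_tol=1e-3 + 1e-9)
    # idempotent after the first quantization
    twice = parse_pdb(write_pdb(once), "A", "B")
    assert structures_close(once, twice, coord_tol=1e-9)


def test_coordinates_serialized_to_three_decimals(toy_dimer):
    s, _ = toy_dimer
    from dataclasses import replace

    res = s.residues[0]
    s.atoms[res][0] = replace(s.atoms[res][0], x=1.23456)
    line = write_pdb(s).splitlines()[0]
    assert "   1.235" in line


def test_backbone_incompleteness_warned():
    incomplete = [
        atom_line(1, "N", "GLY", "A", 1, 0, 0.8, 0),
        atom_line(2, "CA", "GLY", "A", 1, 1.2, 0, 0),
    ] + gly_residue(3, "B", 1, (0, 0, 4.5))
    s = parse_pdb("\n".join(incomplete), "A", "B")
    assert any("missing backbone" in w and "C,O" in w for w in s.warnings)


def test_hydrogens_kept_but_not_heavy(mini_dimer_pdb):
    with_h = mini_dimer_pdb.replace(
        "END", atom_line(40, "HA2", "GLY", "B", 1, 1.2, -0.9, 4.5, element="H") + "\nEND")
    s = parse_pdb(with_h, "A", "B")
    h = [a for r in s.chain_residues("B") for a in s.atoms[r] if a.element == "H"]
    assert len(h) == 1 and not h[0].is_heavy


def test_alt_loc_resolution_never_grows_atom_count():
    raw = gly_residue(1, "A", 1) + [
        atom_line(5, "N", "SER", "B", 1, 0, 0, 4.5),
        atom_line(6, "CA", "SER", "B", 1, 1.0, 0, 4.5, occ=0.6, alt="A"),
        atom_line(7, "CA", "SER", "B", 1, 1.5, 0, 4.5, occ=0.4, alt="B"),
        atom_line(8, "C", "SER", "B", 1, 2.4, 0, 4.5),
        atom_line(9, "O", "SER", "B", 1, 2.4, 1.2, 4.5),
    ]
    n_raw = len(raw)
    s = parse_pdb("\n".join(raw), "A", "B")
    assert sum(len(a) for a in s.atoms.values()) <= n_raw
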