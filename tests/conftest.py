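import numpy as np
import pytest

from proton_scan import ToyDimerSpec, make_toy_dimer


def atom_line(serial, name, resname, chain, seq, x, y, z, occ=1.0, alt="",
              element=None, record="ATOM", icode=""):
    """Format one fixed-column coordinate line for hand-written fixtures."""
    element = element or name[0]
    name_field = f"{name:<4s}" if len(name) >= 4 else f" {name:<3s}"
    return (f"{record:<6s}{serial:>5d} {name_field}{alt or ' ':1s}{resname:>3s} "
            f"{chain:1s}{seq:>4d}{icode or ' ':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}          {element:>2s}")


def gly_residue(serial0, chain, seq, origin=(0.0, 0.0, 0.0)):
    ox, oy, oz = origin
    coords = {"N": (0.0, 0.8, 0.0), "CA": (1.2, 0.0, 0.0),
              "C": (2.45, 0.45, 0.0), "O": (2.75, 1.6, 0.0)}
    return [atom_line(serial0 + i, n, "GLY", chain, seq,
                      ox + c[0], oy + c[1], oz + c[2])
            for i, (n, c) in enumerate(coords.items())]


@pytest.fixture
def mini_dimer_pdb():
    """2 GLY on chain A, 1 GLY on chain B."""
    lines = (gly_residue(1, "A", 1) + gly_residue(5, "A", 2, (3.8, 0, 0))
             + gly_residue(9, "B", 1, (0, 0, 4.5)))
    return "\n".join(lines + ["END"]) + "\n"


@pytest.fixture
def toy_dimer():
    structure, truth = make_toy_dimer(
        ToyDimerSpec(6, 6, 4.5, "LFAKED", "AYWGRH", "two-strands"))
    return structure, truth


def random_toy_spec(rng: np.random.Generator) -> ToyDimerSpec:
    from proton_scan.aminoacids import ALPHABET

    geometry = rng.choice(["two-strands", "helix-pair"])
    na, nb = int(rng.integers(3, 9)), int(rng.integers(3, 9))
    return ToyDimerSpec(
        n_residues_a=na,
        n_residues_b=nb,
        gap=float(rng.uniform(3.5, 6.5)),
        sequence_a="".join(rng.choice(list(ALPHABET), na)),
        sequence_b="".join(rng.choice(list(ALPHABET), nb)),
        geometry=str(geometry),
    )
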