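"""PDB reading/writing and the two-chain structure model.

The whole pipeline operates on a :class:`DimerStructure`: the atoms of
exactly two chains of interest, in author residue numbering (reported
mutations such as F19D or G262A use author numbers, so that numbering is the
canonical coordinate system throughout).

Parsing policy
--------------
* only MODEL 1 of multi-model files (a warning is recorded);
* waters and non-amino-acid HETATM groups (ligands, ions) are dropped;
  amino-acid-like HETATM residues (MSE, ...) are kept with one-letter code
  ``X`` — they participate in distance calculations but are never mutated;
* for alternate locations the highest-occupancy conformer wins, ties broken
  by alphabetically first alt_loc;
* hydrogens are retained as atoms but flagged ``is_heavy=False`` and ignored
  by the interface distance test and the energy terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi

from .aminoacids import one_letter
from .errors import MissingChainError, PdbFormatError

__all__ = [
    "AtomRecord",
    "ResidueRef",
    "DimerStructure",
    "parse_pdb",
    "write_pdb",
    "structures_close",
]

BACKBONE_HEAVY = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class AtomRecord:
    """One atom: PDB-convention name, element, coordinates in Angstrom."""

    serial: int
    name: str
    element: str
    alt_loc: str  # '' if blank
    x: float
    y: float
    z: float
    occupancy: float = 1.0
    is_heavy: bool = True

    @property
    def coord(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass(frozen=True, order=True)
class ResidueRef:
    """A residue identified by chain, author sequence number and insertion code."""

    chain_id: str
    seq_num: int
    insertion_code: str  # '' if blank
    aa3: str
    aa1: str

    @property
    def label(self) -> str:
        """Human label, e.g. ``F19`` or ``X102A`` (icode appended)."""
        return f"{self.aa1}{self.seq_num}{self.insertion_code}"

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_num, self.insertion_code)


@dataclass
class DimerStructure:
    """Atoms of exactly two selected chains, grouped by residue.

    ``residues`` preserves file order; ``atoms[res]`` preserves per-residue
    atom order after alternate-location resolution.
    """

    chain_a_id: str
    chain_b_id: str
    residues: list[ResidueRef]
    atoms: dict[ResidueRef, list[AtomRecord]]
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.chain_a_id == self.chain_b_id:
            raise ValueError("the two chain IDs must differ")
        chains = {r.chain_id for r in self.residues}
        extra = chains - {self.chain_a_id, self.chain_b_id}
        if extra:
            raise ValueError(f"residues from unexpected chains: {sorted(extra)}")
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (chain, seq_num, insertion_code) residue")
        for res, atoms in self.atoms.items():
            seen = {(a.name, a.alt_loc) for a in atoms}
            if len(seen) != len(atoms):
                raise ValueError(f"residue {res.label}: duplicate (name, alt_loc) atom")

    # -- convenience accessors -------------------------------------------------

    def chain_residues(self, chain_id: str) -> list[ResidueRef]:
        return [r for r in self.residues if r.chain_id == chain_id]

    def partner_of(self, chain_id: str) -> str:
        if chain_id == self.chain_a_id:
            return self.chain_b_id
        if chain_id == self.chain_b_id:
            return self.chain_a_id
        raise MissingChainError(chain_id, [self.chain_a_id, self.chain_b_id])

    def find_residue(self, chain_id: str, seq_num: int, insertion_code: str = "") -> ResidueRef:
        for r in self.residues:
            if r.key == (chain_id, seq_num, insertion_code):
                return r
        raise KeyError(f"no residue {chain_id}/{seq_num}{insertion_code}")

    def heavy_atoms(self, chain_id: str) -> list[tuple[ResidueRef, AtomRecord]]:
        out = []
        for res in self.chain_residues(chain_id):
            out.extend((res, a) for a in self.atoms[res] if a.is_heavy)
        return out

    def replace_residue(self, res: ResidueRef, new_res: ResidueRef,
                        new_atoms: list[AtomRecord]) -> "DimerStructure":
        """Return a copy with one residue (and its atoms) swapped out."""
        residues = [new_res if r == res else r for r in self.residues]
        atoms = {(new_res if r == res else r): (new_atoms if r == res else a)
                 for r, a in self.atoms.items()}
        return DimerStructure(self.chain_a_id, self.chain_b_id, residues, atoms,
                              list(self.warnings))


def _is_amino_acid(res: gemmi.Residue) -> bool:
    if res.het_flag == "A":
        return True
    info = gemmi.find_tabulated_residue(res.name)
    return info is not None and info.is_amino_acid()


def _resolve_alt_locs(raw: list[gemmi.Atom]) -> list[gemmi.Atom]:
    """Per atom name keep the highest-occupancy conformer (tie: first alt_loc)."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    order: list[str] = []
    for a in raw:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    kept = []
    for name in order:
        group = by_name[name]
        best = min(group, key=lambda a: (-a.occ, a.altloc))
        kept.append(best)
    return kept


def parse_pdb(text: str, chain_a: str, chain_b: str) -> DimerStructure:
    """Parse a PDB character stream into the two requested chains.

    Raises :class:`MissingChainError` if a chain is absent,
    :class:`PdbFormatError` if no amino-acid coordinates are present, and
    ``ValueError`` if the two chain IDs coincide.
    """
    if chain_a == chain_b:
        raise ValueError("chain_a and chain_b must differ")
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise PdbFormatError(f"could not parse PDB stream: {exc}") from exc
    if len(st) == 0:
        raise PdbFormatError("no coordinate models found in PDB stream")

    warnings: list[str] = []
    if len(st) > 1:
        warnings.append(f"multi-model file: using model 1 of {len(st)}")
    model = st[0]

    n_aa_anywhere = sum(
        1 for chain in model for res in chain
        if _is_amino_acid(res) and not res.is_water())
    if n_aa_anywhere == 0:
        raise PdbFormatError("no ATOM records with amino-acid residues found")

    available = [ch.name for ch in model]
    for want in (chain_a, chain_b):
        if want not in available:
            raise MissingChainError(want, available)

    residues: list[ResidueRef] = []
    atoms: dict[ResidueRef, list[AtomRecord]] = {}
    for chain in model:
        for res in chain:
            if not _is_amino_acid(res) or res.is_water():
                continue
            if chain.name not in (chain_a, chain_b):
                continue
            ref = ResidueRef(
                chain_id=chain.name,
                seq_num=res.seqid.num,
                insertion_code=(res.seqid.icode or "").strip(),
                aa3=res.name,
                aa1=one_letter(res.name),
            )
            records = []
            for a in _resolve_alt_locs(list(res)):
                elem = a.element.name.upper()
                alt = a.altloc if a.altloc not in ("", " ", "\x00") else ""
                records.append(AtomRecord(
                    serial=a.serial,
                    name=a.name,
                    element=elem,
                    alt_loc=alt,
                    x=a.pos.x, y=a.pos.y, z=a.pos.z,
                    occupancy=a.occ,
                    is_heavy=elem not in ("H", "D"),
                ))
            if ref in atoms:  # microheterogeneity: keep the first residue name
                continue
            residues.append(ref)
            atoms[ref] = records

    for ref in residues:
        if ref.aa1 != "X":
            names = {a.name for a in atoms[ref] if a.is_heavy}
            missing = [n for n in BACKBONE_HEAVY if n not in names]
            if missing:
                warnings.append(
                    f"residue {ref.chain_id}/{ref.label}: missing backbone atoms "
                    + ",".join(missing)
                )

    return DimerStructure(chain_a, chain_b, residues, atoms, warnings)


def _format_atom_name(name: str, element: str) -> str:
    # PDB columns 13-16: 2-char elements start at col 13, else col 14.
    if len(name) >= 4 or len(element) == 2:
        return f"{name:<4s}"
    return f" {name:<3s}"


def write_pdb(structure: DimerStructure) -> str:
    """Serialize to fixed-column PDB text (coordinates to 3 decimals).

    Round-trip guarantee: ``parse_pdb(write_pdb(s), a, b)`` reproduces ``s``
    up to the 3-decimal coordinate precision of the format.
    """
    lines = []
    for chain_id in (structure.chain_a_id, structure.chain_b_id):
        last_ref = None
        for res in structure.chain_residues(chain_id):
            for a in structure.atoms[res]:
                lines.append(
                    "ATOM  {serial:>5d} {name}{alt:1s}{res:>3s} {ch:1s}{seq:>4d}{icode:1s}   "
                    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {elem:>2s}".format(
                        serial=a.serial % 100000,
                        name=_format_atom_name(a.name, a.element),
                        alt=a.alt_loc or " ",
                        res=res.aa3,
                        ch=res.chain_id,
                        seq=res.seq_num,
                        icode=res.insertion_code or " ",
                        x=a.x, y=a.y, z=a.z,
                        occ=a.occupancy, b=0.0,
                        elem=a.element,
                    )
                )
            last_ref = res
        if last_ref is not None:
            lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def structures_close(a: DimerStructure, b: DimerStructure, coord_tol: float = 2e-3) -> bool:
    """True if two structures have identical residues/atoms up to coord_tol."""
    if (a.chain_a_id, a.chain_b_id) != (b.chain_a_id, b.chain_b_id):
        return False
    if a.residues != b.residues:
        return False
    for res in a.residues:
        aa, ba = a.atoms[res], b.atoms[res]
        if len(aa) != len(ba):
            return False
        for x, y in zip(aa, ba):
            if (x.name, x.element, x.alt_loc, x.is_heavy) != (y.name, y.element, y.alt_loc, y.is_heavy):
                return False
            if max(abs(x.x - y.x), abs(x.y - y.y), abs(x.z - y.z)) > coord_tol:
                return False
    return True
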