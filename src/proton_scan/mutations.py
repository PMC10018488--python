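"""Saturation-mutagenesis enumeration over interfacial residues.

Every interfacial residue of the analysis chain is substituted with the 19
other standard amino acids, so a scan of N interfacial residues always
yields 19*N candidate mutations. Mutation codes follow the
wild-type/chain/position/mutant convention (``FB19D`` = Phe on chain B at
author position 19 mutated to Asp); an insertion code, when present, is
appended after the number (``FB19AD`` for icode A).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Literal

from .aminoacids import ALPHABET
from .interface_detect import InterfaceResidue

__all__ = ["MutationSpec", "enumerate_mutations", "format_mutation_list",
           "parse_mutation_code", "parse_mutation_list"]

_CODE_RE = re.compile(
    r"^(?P<wt>[A-Y])(?P<chain>[A-Za-z0-9])(?P<num>-?\d+)(?P<icode>[A-Za-z]?)(?P<mut>[A-Y])$"
)


@dataclass(frozen=True, order=True)
class MutationSpec:
    """One candidate point mutation on the analysis chain."""

    chain_id: str
    seq_num: int
    insertion_code: str
    wt_aa1: str
    mut_aa1: str

    def __post_init__(self) -> None:
        for aa in (self.wt_aa1, self.mut_aa1):
            if aa not in ALPHABET:
                raise ValueError(f"{aa!r} is not a standard amino acid")
        if self.wt_aa1 == self.mut_aa1:
            raise ValueError("self-mutations are excluded from the scan")

    @property
    def code(self) -> str:
        return f"{self.wt_aa1}{self.chain_id}{self.seq_num}{self.insertion_code}{self.mut_aa1}"

    @property
    def position_label(self) -> str:
        return f"{self.wt_aa1}{self.seq_num}{self.insertion_code}"


def parse_mutation_code(code: str) -> MutationSpec:
    """Inverse of :attr:`MutationSpec.code`."""
    m = _CODE_RE.match(code.strip())
    if not m:
        raise ValueError(f"unparseable mutation code {code!r}")
    return MutationSpec(
        chain_id=m.group("chain"),
        seq_num=int(m.group("num")),
        insertion_code=m.group("icode"),
        wt_aa1=m.group("wt"),
        mut_aa1=m.group("mut"),
    )


def enumerate_mutations(interface: Iterable[InterfaceResidue]) -> list[MutationSpec]:
    """All 19 substitutions per interfacial residue, in deterministic order.

    Residues follow the interface order (sequence position); substitutions
    follow the fixed alphabet ``ACDEFGHIKLMNPQRSTVWY``. Non-standard
    residues must already have been excluded by interface detection.
    """
    specs: list[MutationSpec] = []
    for ir in interface:
        res = ir.residue
        if res.aa1 == "X":
            raise ValueError(f"non-standard residue {res.label} cannot be mutated")
        for aa in ALPHABET:
            if aa == res.aa1:
                continue
            specs.append(MutationSpec(
                chain_id=res.chain_id,
                seq_num=res.seq_num,
                insertion_code=res.insertion_code,
                wt_aa1=res.aa1,
                mut_aa1=aa,
            ))
    return specs


def format_mutation_list(
    specs: list[MutationSpec],
    dialect: Literal["canonical", "external_scanner"] = "canonical",
) -> str:
    """One mutation code per line; the external-scanner dialect appends ';'
    (the individual-mutation list convention of BuildMutant-style tools)."""
    if not specs:
        raise ValueError("empty mutation list")
    suffix = ";" if dialect == "external_scanner" else ""
    if dialect not in ("canonical", "external_scanner"):
        raise ValueError(f"unknown dialect {dialect!r}")
    return "".join(f"{s.code}{suffix}\n" for s in specs)


def parse_mutation_list(text: str) -> list[MutationSpec]:
    """Parse either dialect back into specs (blank lines ignored)."""
    specs = []
    for line in text.splitlines():
        line = line.strip().rstrip(";")
        if line:
            specs.append(parse_mutation_code(line))
    return specs
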