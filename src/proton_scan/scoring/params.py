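"""Loading of the built-in scorer's parameter file."""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import yaml


@dataclass(frozen=True)
class ScoringParams:
    """Immutable view of one parameter-file version."""

    version: int
    lj_cutoff: float
    lj_cap: float
    lj_radius: dict
    lj_epsilon: dict
    coulomb_constant: float
    dielectric_slope: float
    elec_cutoff: float
    charges: dict  # aa3 -> {atom_name: charge}
    hb_strength: float
    hb_r_full: float
    hb_r_zero: float
    solv_cutoff: float
    solv_s: dict  # element -> burial score
    clash_slope: float
    reference_energies: dict  # aa1 -> e_ref

    def charge_of(self, aa3: str, atom_name: str) -> float:
        return self.charges.get(aa3, {}).get(atom_name, 0.0)

    def e_ref(self, aa1: str) -> float:
        return self.reference_energies.get(aa1, 0.0)


def load_params(path: str | None = None) -> ScoringParams:
    """Load a parameter file; the packaged version-1 file by default."""
    if path is None:
        text = (resources.files("proton_scan.scoring") / "params.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return ScoringParams(
        version=raw["version"],
        lj_cutoff=float(raw["lj"]["cutoff"]),
        lj_cap=float(raw["lj"]["repulsion_cap"]),
        lj_radius={k: float(v) for k, v in raw["lj"]["radius"].items()},
        lj_epsilon={k: float(v) for k, v in raw["lj"]["epsilon"].items()},
        coulomb_constant=float(raw["electrostatics"]["coulomb_constant"]),
        dielectric_slope=float(raw["electrostatics"]["dielectric_slope"]),
        elec_cutoff=float(raw["electrostatics"]["cutoff"]),
        charges=raw["electrostatics"]["charges"],
        hb_strength=float(raw["hbond"]["strength"]),
        hb_r_full=float(raw["hbond"]["r_full"]),
        hb_r_zero=float(raw["hbond"]["r_zero"]),
        solv_cutoff=float(raw["solvation"]["cutoff"]),
        solv_s={k: float(v) for k, v in raw["solvation"]["s"].items()},
        clash_slope=float(raw["clash"]["slope"]),
        reference_energies={k: float(v) for k, v in raw["reference_energies"].items()},
    )


_DEFAULT: ScoringParams | None = None


def default_params() -> ScoringParams:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_params()
    return _DEFAULT
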