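"""Independent reference computations used by the tests.

Everything here is deliberately written with plain Python loops and its own
reading of the parameter file, so it shares no code path with the package
implementation it checks.
"""

import math
from importlib import resources

import yaml


def load_raw_params() -> dict:
    text = (resources.files("proton_scan.scoring") / "params.yaml").read_text()
    return yaml.safe_load(text)


def brute_force_interface(structure, analysis_chain, cutoff):
    """All-pairs O(N*M) heavy-atom interface scan."""
    partner = (structure.chain_a_id if analysis_chain == structure.chain_b_id
               else structure.chain_b_id)
    partner_atoms = [a for r in structure.chain_residues(partner)
                     for a in structure.atoms[r] if a.is_heavy]
    found = []
    for res in structure.chain_residues(analysis_chain):
        dmin = math.inf
        for a in structure.atoms[res]:
            if not a.is_heavy:
                continue
            for b in partner_atoms:
                d = math.sqrt((a.x - b.x) ** 2 + (a.y - b.y) ** 2 + (a.z - b.z) ** 2)
                dmin = min(dmin, d)
        if dmin <= cutoff:
            found.append(res)
    return found


def _etype(element):
    if element in ("C", "N", "O", "S"):
        return element
    return "S" if element == "SE" else "C"


def pair_terms(atoms1, atoms2, raw=None, exclude=frozenset(), with_solv=True):
    """Loop-based recomputation of the pairwise energy terms.

    ``atoms1``/``atoms2`` are lists of (aa3, AtomRecord); ``exclude`` holds
    (i, j) index pairs to omit.
    """
    raw = raw or load_raw_params()
    lj, el = raw["lj"], raw["electrostatics"]
    hb, sv, cl = raw["hbond"], raw["solvation"], raw["clash"]
    out = {"e_vdw": 0.0, "e_elec": 0.0, "e_hbond": 0.0, "e_solv": 0.0, "e_clash": 0.0}
    for i, (aa3_i, a) in enumerate(atoms1):
        for j, (aa3_j, b) in enumerate(atoms2):
            if (i, j) in exclude:
                continue
            r = math.sqrt((a.x - b.x) ** 2 + (a.y - b.y) ** 2 + (a.z - b.z) ** 2)
            r = max(r, 1e-6)
            ti, tj = _etype(a.element), _etype(b.element)
            rmin = lj["radius"][ti] + lj["radius"][tj]
            if r <= lj["cutoff"]:
                eps = math.sqrt(lj["epsilon"][ti] * lj["epsilon"][tj])
                e = eps * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6)
                out["e_vdw"] += min(e, lj["repulsion_cap"])
            qi = el["charges"].get(aa3_i, {}).get(a.name, 0.0)
            qj = el["charges"].get(aa3_j, {}).get(b.name, 0.0)
            if qi * qj != 0.0 and r <= el["cutoff"]:
                out["e_elec"] += (el["coulomb_constant"] * qi * qj
                                  / (el["dielectric_slope"] * r * r))
            if ti in ("N", "O") and tj in ("N", "O") and r < hb["r_zero"]:
                ramp = min(1.0, (hb["r_zero"] - r) / (hb["r_zero"] - hb["r_full"]))
                out["e_hbond"] += hb["strength"] * ramp
            if with_solv and r <= sv["cutoff"]:
                out["e_solv"] += sv["s"][ti] + sv["s"][tj]
            if r < rmin:
                out["e_clash"] += cl["slope"] * (rmin - r)
    return out


def quartiles_linear(values):
    """Quartiles by linear interpolation between order statistics."""
    v = sorted(values)
    n = len(v)

    def q(p):
        pos = p * (n - 1)
        lo = math.floor(pos)
        hi = math.ceil(pos)
        return v[lo] + (pos - lo) * (v[hi] - v[lo])

    return q(0.25), q(0.5), q(0.75)
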