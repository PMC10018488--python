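"""Scoring backends: the built-in term-level scorer and external-score adapters.

Every backend satisfies the same contract: ``score_all(structure, specs)``
returns exactly one :class:`MutationScore` per input spec, in input order.
A mutation whose model cannot be built is recorded with a failed status
rather than aborting the scan — one bad position must not kill a
700-mutation landscape.

External adapters ingest score tables produced by running the established
interface scanners (EvoEF1- or FoldX-style command-line tools) outside this
package; scores from different backends are never mixed in one landscape.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Protocol, runtime_checkable

from ..errors import DataError, ModelError
from ..mutations import MutationSpec, parse_mutation_code
from ..structure_io import DimerStructure
from .energy import EnergyBreakdown, binding_energy, stability_score
from .mutant import build_mutant_model
from .params import ScoringParams, default_params

__all__ = ["MutationScore", "ScoringBackend", "BuiltinScorer", "TableBackend",
           "ingest_external_scores", "scores_table"]


@dataclass(frozen=True)
class MutationScore:
    """Binding ddG and stability change of one mutation (mutant minus wild type)."""

    mutation: MutationSpec
    ddg_bind: float
    stability: float
    breakdown_wt: EnergyBreakdown | None = None
    breakdown_mut: EnergyBreakdown | None = None
    status: str = "ok"
    backend: str = "builtin"

    @property
    def ok(self) -> bool:
        return self.status == "ok"


@runtime_checkable
class ScoringBackend(Protocol):
    name: str
    deterministic: bool

    def score_all(self, structure: DimerStructure,
                  specs: list[MutationSpec]) -> list[MutationScore]: ...


class BuiltinScorer:
    """Deterministic built-in scorer.

    ``ddg_bind`` is the interchain binding total of the mutant model minus
    that of the wild type; ``stability`` is the mutated residue's local
    environment score in the mutant minus in the wild type. Identical
    inputs give bitwise-identical outputs.
    """

    name = "builtin"
    deterministic = True

    def __init__(self, params: ScoringParams | None = None):
        self.params = params or default_params()

    def score_one(self, structure: DimerStructure, spec: MutationSpec,
                  wt_total: float | None = None,
                  wt_breakdown: EnergyBreakdown | None = None) -> MutationScore:
        if wt_breakdown is None:
            wt_breakdown = binding_energy(structure, self.params)
        try:
            wt_res = structure.find_residue(spec.chain_id, spec.seq_num,
                                            spec.insertion_code)
            wt_stab = stability_score(structure, wt_res, self.params)
            mutant = build_mutant_model(structure, spec, self.params)
            mut_res = mutant.find_residue(spec.chain_id, spec.seq_num,
                                          spec.insertion_code)
            mut_breakdown = binding_energy(mutant, self.params)
            mut_stab = stability_score(mutant, mut_res, self.params)
        except (ModelError, KeyError) as exc:
            return MutationScore(spec, math.nan, math.nan, status=f"failed: {exc}",
                                 backend=self.name)
        return MutationScore(
            mutation=spec,
            ddg_bind=mut_breakdown.total - wt_breakdown.total,
            stability=mut_stab - wt_stab,
            breakdown_wt=wt_breakdown,
            breakdown_mut=mut_breakdown,
            backend=self.name,
        )

    def score_all(self, structure: DimerStructure,
                  specs: list[MutationSpec]) -> list[MutationScore]:
        wt_breakdown = binding_energy(structure, self.params)
        return [self.score_one(structure, s, wt_breakdown=wt_breakdown)
                for s in specs]


Dialect = Literal["generic_csv", "evoef1_log", "foldx_tab"]


def _parse_rows(text: str, dialect: Dialect) -> list[tuple[int, str, str, str]]:
    """Yield (line_number, code, ddg_field, stability_field) triples."""
    rows = []
    if dialect == "generic_csv":
        reader = csv.reader(io.StringIO(text))
        for lineno, row in enumerate(reader, start=1):
            if not row or not any(f.strip() for f in row):
                continue
            if lineno == 1 and row[0].strip().lower() == "mutation":
                continue
            if len(row) < 3:
                raise DataError(f"line {lineno}: expected mutation,ddg_bind,stability")
            rows.append((lineno, row[0].strip(), row[1], row[2]))
    elif dialect == "evoef1_log":
        # whitespace-delimited "CODE ddg stability", '#' comments allowed
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise DataError(f"line {lineno}: expected 'mutation ddg stability'")
            rows.append((lineno, parts[0].rstrip(";"), parts[1], parts[2]))
    elif dialect == "foldx_tab":
        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if lineno == 1 and parts[0].strip().lower() == "mutation":
                continue
            if len(parts) < 3:
                raise DataError(f"line {lineno}: expected mutation<TAB>ddg<TAB>stability")
            rows.append((lineno, parts[0].strip(), parts[1], parts[2]))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return rows


def ingest_external_scores(text: str, dialect: Dialect = "generic_csv",
                           expected: Iterable[MutationSpec] | None = None,
                           backend_name: str | None = None) -> list[MutationScore]:
    """Parse an externally produced mutation-score table.

    When ``expected`` is given, the table's mutation codes must match the
    enumerated scan exactly; offenders (unknown or missing codes) are
    listed in the error. Term breakdowns are absent for external scores.
    """
    name = backend_name or dialect
    scores = []
    for lineno, code, ddg_s, stab_s in _parse_rows(text, dialect):
        try:
            spec = parse_mutation_code(code)
        except ValueError as exc:
            raise DataError(f"line {lineno}: {exc}") from exc
        try:
            ddg, stab = float(ddg_s), float(stab_s)
        except ValueError:
            raise DataError(
                f"line {lineno}: malformed numeric field in ({ddg_s!r}, {stab_s!r})"
            ) from None
        scores.append(MutationScore(spec, ddg, stab, backend=name))

    if expected is not None:
        want = {s.code for s in expected}
        got = {s.mutation.code for s in scores}
        unknown = sorted(got - want)
        missing = sorted(want - got)
        if unknown or missing:
            raise DataError(
                "score table does not match the enumerated scan; "
                f"unknown codes: {unknown or 'none'}; missing codes: {missing or 'none'}"
            )
    return scores


class TableBackend:
    """Backend serving pre-computed external scores by mutation code."""

    deterministic = True

    def __init__(self, text: str, dialect: Dialect = "generic_csv",
                 name: str | None = None):
        self.name = name or f"csv:{dialect}"
        self._text = text
        self._dialect = dialect

    def score_all(self, structure: DimerStructure,
                  specs: list[MutationSpec]) -> list[MutationScore]:
        parsed = ingest_external_scores(self._text, self._dialect,
                                        expected=specs, backend_name=self.name)
        by_code = {s.mutation.code: s for s in parsed}
        return [by_code[s.code] for s in specs]


def scores_table(scores: list[MutationScore]):
    """Scores as a DataFrame in the scan's CSV column contract."""
    import pandas as pd

    return pd.DataFrame({
        "mutation": [s.mutation.code for s in scores],
        "position": [f"{s.mutation.seq_num}{s.mutation.insertion_code}" for s in scores],
        "wt_aa": [s.mutation.wt_aa1 for s in scores],
        "mut_aa": [s.mutation.mut_aa1 for s in scores],
        "ddg_bind": [s.ddg_bind for s in scores],
        "stability": [s.stability for s in scores],
        "status": [s.status for s in scores],
        "backend": [s.backend for s in scores],
    })
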