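"""Designer-mutation selection: stability and optional PSSM filtering.

Outlier mutations are promoted to *designer* mutations only if they pass:

1. the stability rule — keep a mutation iff its stability score is
   strictly < 0 (the mutated residue does not destabilize the fold);
2. optionally the evolutionary rule against a user-supplied PSSM
   (log-odds-like: positive = favored by evolution) — keep a *depleting*
   mutation iff its PSSM score is <= 0, keep an *enriching* mutation iff
   its PSSM score is > 0. Note the deliberate asymmetry at zero.

Both rules are per-mutation predicates, so their composition is
order-independent; they are applied stability-first by convention. Every
outlier is retained in the report with explicit pass/fail provenance flags
for each filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import pandas as pd

from .aminoacids import ALPHABET
from .errors import DataError
from .mutations import MutationSpec
from .outlier_stats import OutlierClassification
from .scoring.backends import MutationScore

__all__ = ["PssmTable", "DesignerRecord", "DesignerSet",
           "parse_pssm_csv", "write_pssm_csv", "stability_filter", "pssm_filter"]


@dataclass(frozen=True)
class PssmTable:
    """Per-position, per-amino-acid evolutionary scores (author numbering)."""

    scores: dict  # (seq_num, aa1) -> float
    positions: tuple  # ordered seq_nums covered

    def __getitem__(self, key: tuple[int, str]) -> float:
        return self.scores[key]

    def covers(self, seq_num: int) -> bool:
        return seq_num in self.positions


def parse_pssm_csv(text: str) -> PssmTable:
    """Parse a PSSM CSV: a position column followed by 20 amino-acid columns."""
    import io

    df = pd.read_csv(io.StringIO(text))
    cols = {c.strip().upper(): c for c in df.columns[1:]}
    missing = [aa for aa in ALPHABET if aa not in cols]
    if missing:
        raise DataError(f"PSSM CSV missing amino-acid column(s): {','.join(missing)}")
    pos_col = df.columns[0]
    positions = [int(p) for p in df[pos_col]]
    if len(positions) != len(set(positions)):
        dups = sorted({p for p in positions if positions.count(p) > 1})
        raise DataError(f"PSSM CSV has duplicate position(s): {dups}")
    scores = {}
    for _, row in df.iterrows():
        p = int(row[pos_col])
        for aa in ALPHABET:
            try:
                scores[(p, aa)] = float(row[cols[aa]])
            except (TypeError, ValueError):
                raise DataError(
                    f"PSSM position {p}, column {aa}: malformed value {row[cols[aa]]!r}"
                ) from None
    return PssmTable(scores=scores, positions=tuple(positions))


def write_pssm_csv(table: PssmTable) -> str:
    rows = [{"position": p, **{aa: table[(p, aa)] for aa in ALPHABET}}
            for p in table.positions]
    return pd.DataFrame(rows).to_csv(index=False)


@dataclass(frozen=True)
class DesignerRecord:
    """One outlier mutation with its scores and filter provenance."""

    mutation: MutationSpec
    label: str  # 'enriching' | 'depleting'
    ddg_bind: float
    stability: float
    passed_stability: bool
    passed_pssm: bool | None  # None = not applicable (no PSSM supplied)

    @property
    def kept(self) -> bool:
        return self.passed_stability and self.passed_pssm is not False


@dataclass
class DesignerSet:
    """All outliers with provenance; the final set is the kept subset."""

    records: list[DesignerRecord]

    @property
    def enriching_final(self) -> list[DesignerRecord]:
        return [r for r in self.records if r.label == "enriching" and r.kept]

    @property
    def depleting_final(self) -> list[DesignerRecord]:
        return [r for r in self.records if r.label == "depleting" and r.kept]

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "mutation": [r.mutation.code for r in self.records],
            "label": [r.label for r in self.records],
            "ddg_bind": [r.ddg_bind for r in self.records],
            "stability": [r.stability for r in self.records],
            "passed_stability": [r.passed_stability for r in self.records],
            "passed_pssm": ["n/a" if r.passed_pssm is None else r.passed_pssm
                            for r in self.records],
            "kept": [r.kept for r in self.records],
        })


def stability_filter(outliers: OutlierClassification,
                     scores: list[MutationScore]) -> DesignerSet:
    """Apply the stability keep-rule (< 0, strict) to every outlier.

    Raises :class:`DataError` if an outlier mutation has no (finite)
    stability score.
    """
    by_spec = {s.mutation: s for s in scores}
    records = []
    for label, specs in (("enriching", outliers.enriching),
                         ("depleting", outliers.depleting)):
        for spec in specs:
            score = by_spec.get(spec)
            if score is None or not math.isfinite(score.stability):
                raise DataError(f"outlier {spec.code} has no stability score")
            records.append(DesignerRecord(
                mutation=spec,
                label=label,
                ddg_bind=score.ddg_bind,
                stability=score.stability,
                passed_stability=score.stability < 0.0,
                passed_pssm=None,
            ))
    return DesignerSet(records=records)


def pssm_filter(designer: DesignerSet, pssm: PssmTable | None) -> DesignerSet:
    """Apply the evolutionary keep-rules; a no-op (flags n/a) without a PSSM.

    Raises :class:`DataError` when the PSSM does not cover every outlier
    position.
    """
    if pssm is None:
        return designer
    uncovered = sorted({r.mutation.seq_num for r in designer.records
                        if not pssm.covers(r.mutation.seq_num)})
    if uncovered:
        raise DataError(f"PSSM does not cover interface position(s): {uncovered}")
    records = []
    for r in designer.records:
        value = pssm[(r.mutation.seq_num, r.mutation.mut_aa1)]
        passed = (value <= 0.0) if r.label == "depleting" else (value > 0.0)
        records.append(replace(r, passed_pssm=passed))
    return DesignerSet(records=records)
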