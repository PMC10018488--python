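"""Box-and-whisker outlier detection on a scanned mutation landscape.

The pooled ddG values of the scan (all positions x 19 substitutions) are
summarized by quartiles; whiskers extend k*IQR beyond the box (k = 1.5 by
default). Values falling outside the whiskers are outliers: far-negative
ddG marks *enriching* mutations (much tighter binding), far-positive ddG
marks *depleting* ones.

Two statistically sensitive conventions are explicit configuration here
because they change outlier membership at the margin:

* quantile convention — linear interpolation between order statistics
  (numpy's ``method="linear"``, the common "type 7" rule) by default;
* boundary strictness — a value exactly on a whisker is *not* an outlier
  by default ("falling outside" read as a strict inequality).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import StatisticsError
from .mutations import MutationSpec
from .scoring.backends import MutationScore

__all__ = ["OutlierClassification", "classify_outliers", "CLI_IQR_RANGE"]

CLI_IQR_RANGE = (1.5, 2.5)


@dataclass
class OutlierClassification:
    """Quartiles, whisker bounds and outlier labels of one landscape."""

    q1: float
    median: float
    q3: float
    iqr: float
    k: float
    lower_whisker: float
    upper_whisker: float
    enriching: list[MutationSpec]
    depleting: list[MutationSpec]
    n: int
    quantile_method: str = "linear"
    strict_boundary: bool = True
    ddg_by_code: dict = field(default_factory=dict, repr=False)

    def stats_dict(self) -> dict:
        return {
            "n": self.n, "k": self.k,
            "q1": self.q1, "median": self.median, "q3": self.q3,
            "iqr": self.iqr,
            "lower_whisker": self.lower_whisker,
            "upper_whisker": self.upper_whisker,
            "n_enriching": len(self.enriching),
            "n_depleting": len(self.depleting),
            "quantile_method": self.quantile_method,
            "strict_boundary": self.strict_boundary,
        }


def classify_outliers(scores: list[MutationScore], k: float = 1.5,
                      quantile_method: str = "linear",
                      strict_boundary: bool = True) -> OutlierClassification:
    """Label enriching/depleting outlier mutations of a scanned landscape.

    Failed-status mutations are excluded from the sample. Requires at
    least four finite ddG values; raises :class:`StatisticsError`
    otherwise (use a larger interface or cutoff).
    """
    if k < 1.0:
        raise ValueError("IQR multiplier k must be >= 1.0")
    usable = [s for s in scores if s.ok and math.isfinite(s.ddg_bind)]
    values = np.array([s.ddg_bind for s in usable], dtype=float)
    if values.size < 4:
        raise StatisticsError(
            f"only {values.size} finite ddG values; box-and-whisker statistics "
            "needs at least 4 — consider a larger interface or distance cutoff"
        )
    q1, med, q3 = (float(np.quantile(values, q, method=quantile_method))
                   for q in (0.25, 0.5, 0.75))
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr

    if strict_boundary:
        enr = [s for s in usable if s.ddg_bind < lo]
        dep = [s for s in usable if s.ddg_bind > hi]
    else:
        enr = [s for s in usable if s.ddg_bind <= lo]
        dep = [s for s in usable if s.ddg_bind >= hi]

    # deterministic label order regardless of input order
    def order(ss: list[MutationScore]) -> list[MutationSpec]:
        return [s.mutation for s in sorted(ss, key=lambda s: (s.mutation.seq_num,
                                                              s.mutation.insertion_code,
                                                              s.mutation.mut_aa1))]

    return OutlierClassification(
        q1=q1, median=med, q3=q3, iqr=iqr, k=k,
        lower_whisker=lo, upper_whisker=hi,
        enriching=order(enr), depleting=order(dep),
        n=int(values.size),
        quantile_method=quantile_method,
        strict_boundary=strict_boundary,
        ddg_by_code={s.mutation.code: s.ddg_bind for s in usable},
    )
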