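"""Run summaries, heatmap/per-position tables and static figures.

All figure data is also emitted as CSV/JSON, so the static images are a
convenience, never the only record of a result.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .aminoacids import ALPHABET
from .outlier_stats import OutlierClassification
from .scoring.backends import MutationScore

__all__ = ["RunSummary", "heatmap_matrix", "per_position_summary",
           "save_heatmap_figure", "save_boxplot_figure", "save_per_position_figure"]


@dataclass
class RunSummary:
    """Headline numbers of one scan, plus the parameters that produced them."""

    n_interface_residues: int
    n_mutations_scanned: int
    n_failed: int
    n_enriching_outliers: int
    n_depleting_outliers: int
    n_enriching_final: int
    n_depleting_final: int
    parameters: dict

    def to_dict(self) -> dict:
        return asdict(self)


def _position_key(spec) -> tuple[int, str]:
    return (spec.seq_num, spec.insertion_code)


def heatmap_matrix(scores: list[MutationScore]) -> pd.DataFrame:
    """Position x amino-acid grid of ddG values.

    Rows are interface positions in sequence order (labelled wild type +
    number), columns the fixed 20-letter alphabet. Wild-type cells are the
    reference (0.0); mutations with failed status are missing (NaN).
    """
    positions: list[tuple[int, str]] = []
    labels: dict[tuple[int, str], str] = {}
    for s in scores:
        key = _position_key(s.mutation)
        if key not in labels:
            positions.append(key)
            labels[key] = s.mutation.position_label
    positions.sort()
    grid = pd.DataFrame(np.nan, index=[labels[k] for k in positions],
                        columns=list(ALPHABET))
    wt_of = {}
    for s in scores:
        key = _position_key(s.mutation)
        wt_of[key] = s.mutation.wt_aa1
        if s.ok:
            grid.loc[labels[key], s.mutation.mut_aa1] = s.ddg_bind
    for key in positions:
        grid.loc[labels[key], wt_of[key]] = 0.0
    grid.index.name = "position"
    return grid


def per_position_summary(scores: list[MutationScore],
                         classification: OutlierClassification) -> pd.DataFrame:
    """Per interface residue: ddG spread and outlier counts."""
    enr = {m.code for m in classification.enriching}
    dep = {m.code for m in classification.depleting}
    rows = []
    seen: list[tuple[int, str]] = []
    by_pos: dict[tuple[int, str], list[MutationScore]] = {}
    for s in scores:
        key = _position_key(s.mutation)
        if key not in by_pos:
            seen.append(key)
            by_pos[key] = []
        by_pos[key].append(s)
    for key in sorted(seen):
        group = by_pos[key]
        ok = [s.ddg_bind for s in group if s.ok]
        n_e = sum(1 for s in group if s.mutation.code in enr)
        n_d = sum(1 for s in group if s.mutation.code in dep)
        rows.append({
            "position": group[0].mutation.position_label,
            "min_ddg": min(ok) if ok else np.nan,
            "median_ddg": float(np.median(ok)) if ok else np.nan,
            "max_ddg": max(ok) if ok else np.nan,
            "n_enriching": n_e,
            "n_depleting": n_d,
            "has_outlier": bool(n_e or n_d),
        })
    return pd.DataFrame(rows)


def _agg():
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    return plt


def save_heatmap_figure(grid: pd.DataFrame, path: str) -> None:
    plt = _agg()
    fig, ax = plt.subplots(figsize=(9, max(2.0, 0.35 * len(grid))))
    im = ax.imshow(grid.to_numpy(dtype=float), aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(len(grid.columns)), grid.columns)
    ax.set_yticks(range(len(grid.index)), grid.index)
    ax.set_xlabel("mutant amino acid")
    ax.set_ylabel("interface position")
    fig.colorbar(im, ax=ax, label="ddG (energy units)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_boxplot_figure(classification: OutlierClassification, path: str) -> None:
    plt = _agg()
    values = list(classification.ddg_by_code.values())
    fig, ax = plt.subplots(figsize=(3.2, 4.5))
    ax.boxplot(values, whis=classification.k)
    ax.axhline(classification.upper_whisker, ls="--", lw=0.8, color="purple")
    ax.axhline(classification.lower_whisker, ls="--", lw=0.8, color="purple")
    ax.set_ylabel("ddG (energy units)")
    ax.set_xticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_per_position_figure(scores: list[MutationScore],
                             classification: OutlierClassification,
                             path: str) -> None:
    plt = _agg()
    table = per_position_summary(scores, classification)
    groups: dict[str, list[float]] = {}
    for s in scores:
        if s.ok:
            groups.setdefault(s.mutation.position_label, []).append(s.ddg_bind)
    order = list(table["position"])
    fig, ax = plt.subplots(figsize=(max(4.0, 0.5 * len(order)), 4.0))
    for i, pos in enumerate(order):
        ys = groups.get(pos, [])
        ax.plot([i] * len(ys), ys, "o", ms=3, alpha=0.6, color="steelblue")
    ax.axhline(classification.upper_whisker, ls="--", lw=0.8, color="purple")
    ax.axhline(classification.lower_whisker, ls="--", lw=0.8, color="purple")
    ax.set_xticks(range(len(order)), order, rotation=90)
    ax.set_ylabel("ddG (energy units)")
    ax.set_xlabel("interface position")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
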