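"""End-to-end orchestration: parse -> interface -> enumerate -> score ->
classify -> filter -> report.

``run_pipeline`` executes the whole scan and writes every artifact (CSV
tables, JSON stats, static figures, a parameter log) into the output
directory. Apart from the timestamped log, outputs are byte-reproducible:
running the same configuration twice yields identical tables.
"""

from __future__ import annotations

import datetime
import json
import warnings as _warnings
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .errors import ProtonScanError
from .filters import parse_pssm_csv, pssm_filter, stability_filter
from .interface_detect import InterfaceParams, detect_interface, interface_table
from .mutations import enumerate_mutations, format_mutation_list
from .outlier_stats import classify_outliers
from .report import (RunSummary, heatmap_matrix, per_position_summary,
                     save_boxplot_figure, save_heatmap_figure,
                     save_per_position_figure)
from .scoring import BuiltinScorer, TableBackend, scores_table
from .structure_io import parse_pdb

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

EXIT_SUCCESS, EXIT_PARTIAL = 0, 3


@dataclass
class RunConfig:
    """Everything one scan needs; mirrors the CLI options."""

    pdb_path: str
    chain_a: str
    chain_b: str
    analysis_chain: str
    cutoff: float = 5.0
    iqr_k: float = 1.5
    pssm_path: str | None = None
    backend: str = "builtin"  # 'builtin' or 'csv:<path>'
    output_dir: str = "proton_scan_out"
    quantile_method: str = "linear"
    strict_boundary: bool = True
    make_figures: bool = True
    write_mutant_models: bool = False  # emit mutant PDBs (builtin backend only)
    seed: int = 0  # reserved; every current path is deterministic

    def __post_init__(self) -> None:
        if self.analysis_chain not in (self.chain_a, self.chain_b):
            raise ValueError("analysis_chain must be one of the two selected chains")


@dataclass
class PipelineResult:
    summary: RunSummary
    exit_code: int
    output_dir: Path
    failed_mutations: list[str] = field(default_factory=list)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except ProtonScanError as exc:
                raise type(exc)(f"[stage {name}] {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> PipelineResult:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = []

    def log(msg: str) -> None:
        stamp = datetime.datetime.now().isoformat(timespec="seconds")
        log_lines.append(f"{stamp} {msg}")

    log(f"proton-scan {__version__} starting")
    log(f"parameters: {json.dumps({k: str(v) for k, v in vars(config).items()}, sort_keys=True)}")

    text = Path(config.pdb_path).read_text()
    structure = _stage("parse")(parse_pdb)(text, config.chain_a, config.chain_b)
    for w in structure.warnings:
        log(f"parse warning: {w}")

    params = InterfaceParams(analysis_chain=config.analysis_chain, cutoff=config.cutoff)
    interface = _stage("interface")(detect_interface)(structure, params)
    interface_table(interface).to_csv(out / "interface.csv", index=False)
    if not interface:
        log("warning: empty interface at this cutoff")
        _warnings.warn("empty interface: no residue within the cutoff")

    mutable = [ir for ir in interface if ir.residue.aa1 != "X"]
    if len(mutable) < len(interface):
        skipped = [ir.residue.label for ir in interface if ir.residue.aa1 == "X"]
        log(f"warning: non-standard residues excluded from the scan: {skipped}")
    specs = _stage("enumerate")(enumerate_mutations)(mutable)
    if specs:
        (out / "mutation_list.txt").write_text(format_mutation_list(specs))

    if config.backend == "builtin":
        backend = BuiltinScorer()
    elif config.backend.startswith("csv:"):
        backend = TableBackend(Path(config.backend[4:]).read_text())
    else:
        raise ValueError(f"unknown backend {config.backend!r}")
    scores = _stage("score")(backend.score_all)(structure, specs)
    scores_table(scores).to_csv(out / "scores.csv", index=False)
    if config.write_mutant_models and isinstance(backend, BuiltinScorer):
        from .scoring import build_mutant_model
        from .structure_io import write_pdb

        mut_dir = out / "mutant_models"
        mut_dir.mkdir(exist_ok=True)
        for s in scores:
            if s.ok:
                model = build_mutant_model(structure, s.mutation)
                (mut_dir / f"{s.mutation.code}.pdb").write_text(write_pdb(model))
    failed = [s.mutation.code for s in scores if not s.ok]
    for code in failed:
        log(f"warning: mutation {code} failed to score")

    classification = _stage("classify")(classify_outliers)(
        scores, k=config.iqr_k, quantile_method=config.quantile_method,
        strict_boundary=config.strict_boundary)
    (out / "boxplot_stats.json").write_text(
        json.dumps(classification.stats_dict(), indent=2, sort_keys=True) + "\n")
    outlier_rows = (
        [{"mutation": m.code, "ddg_bind": classification.ddg_by_code[m.code],
          "label": "enriching"} for m in classification.enriching]
        + [{"mutation": m.code, "ddg_bind": classification.ddg_by_code[m.code],
            "label": "depleting"} for m in classification.depleting]
    )
    import pandas as pd
    pd.DataFrame(outlier_rows, columns=["mutation", "ddg_bind", "label"]).to_csv(
        out / "outliers.csv", index=False)

    designer = _stage("stability-filter")(stability_filter)(classification, scores)
    pssm = None
    if config.pssm_path:
        pssm = _stage("pssm-parse")(parse_pssm_csv)(Path(config.pssm_path).read_text())
    designer = _stage("pssm-filter")(pssm_filter)(designer, pssm)
    designer.table().to_csv(out / "designer_set.csv", index=False)

    grid = heatmap_matrix(scores)
    grid.to_csv(out / "heatmap.csv")
    per_pos = per_position_summary(scores, classification)
    per_pos.to_csv(out / "per_position.csv", index=False)
    if config.make_figures:
        save_heatmap_figure(grid, str(out / "heatmap.png"))
        save_boxplot_figure(classification, str(out / "boxplot.png"))
        save_per_position_figure(scores, classification, str(out / "per_position.png"))

    summary = RunSummary(
        n_interface_residues=len(mutable),
        n_mutations_scanned=len(specs),
        n_failed=len(failed),
        n_enriching_outliers=len(classification.enriching),
        n_depleting_outliers=len(classification.depleting),
        n_enriching_final=len(designer.enriching_final),
        n_depleting_final=len(designer.depleting_final),
        parameters={
            "pdb_path": str(config.pdb_path),
            "chain_a": config.chain_a, "chain_b": config.chain_b,
            "analysis_chain": config.analysis_chain,
            "cutoff": config.cutoff, "iqr_k": config.iqr_k,
            "backend": backend.name,
            "pssm": bool(pssm),
            "quantile_method": config.quantile_method,
            "strict_boundary": config.strict_boundary,
        },
    )
    (out / "summary.json").write_text(
        json.dumps(summary.to_dict(), indent=2, sort_keys=True) + "\n")
    log(f"summary: {json.dumps(summary.to_dict()['parameters'], sort_keys=True)}")
    log("done")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")

    return PipelineResult(
        summary=summary,
        exit_code=EXIT_PARTIAL if failed else EXIT_SUCCESS,
        output_dir=out,
        failed_mutations=failed,
    )
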