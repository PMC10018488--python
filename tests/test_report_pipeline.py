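import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from proton_scan import (LandscapeSpec, RunConfig, ToyDimerSpec, classify_outliers,
                         heatmap_matrix, make_synthetic_landscape, make_toy_dimer,
                         per_position_summary, run_pipeline, write_pdb)
from proton_scan.aminoacids import ALPHABET


@pytest.fixture(scope="module")
def landscape():
    spec = LandscapeSpec(n_positions=11, seed=19,
                         planted=((7, "W", 50.0), (2, "Y", -50.0)))
    return make_synthetic_landscape(spec)


def test_heatmap_grid_matches_scores_exhaustively(landscape):
    grid = heatmap_matrix(landscape)
    assert grid.shape == (11, 20)
    for s in landscape:
        row = s.mutation.position_label
        assert grid.loc[row, s.mutation.mut_aa1] == pytest.approx(s.ddg_bind)
    # wild-type reference cells are zero
    for s in landscape:
        assert grid.loc[s.mutation.position_label, s.mutation.wt_aa1] == 0.0


def test_heatmap_failed_cells_missing(landscape):
    from dataclasses import replace

    broken = [replace(landscape[0], status="failed: boom")] + landscape[1:]
    grid = heatmap_matrix(broken)
    first = landscape[0].mutation
    assert math.isnan(grid.loc[first.position_label, first.mut_aa1])
    filled = int(grid.notna().sum().sum())
    assert filled == 11 * 20 - 1  # every cell but the failed one


def test_per_position_outlier_counts_conserve(landscape):
    c = classify_outliers(landscape)
    table = per_position_summary(landscape, c)
    assert table["n_enriching"].sum() == len(c.enriching)
    assert table["n_depleting"].sum() == len(c.depleting)
    planted = table.set_index("position")
    row7 = planted.loc[[p for p in planted.index if p.endswith("7")][0]]
    assert row7["has_outlier"] and row7["n_depleting"] >= 1
    quiet = planted[(planted.n_enriching == 0) & (planted.n_depleting == 0)]
    assert (~quiet.has_outlier).all()


@pytest.fixture(scope="module")
def toy_run(tmp_path_factory):
    base = tmp_path_factory.mktemp("run")
    s, _ = make_toy_dimer(ToyDimerSpec(6, 3, 4.5, "LFAKED", "WYR"))
    pdb = base / "toy.pdb"
    pdb.write_text(write_pdb(s))
    config = RunConfig(str(pdb), "A", "B", "B", output_dir=str(base / "out"),
                       make_figures=True)
    return config, run_pipeline(config)


def test_pipeline_counts_follow_cardinality_law(toy_run):
    _, result = toy_run
    s = result.summary
    assert s.n_interface_residues == 3
    assert s.n_mutations_scanned == 57  # 3 x 19
    assert result.exit_code == 0 and s.n_failed == 0


def test_pipeline_outputs_are_byte_identical_across_runs(toy_run, tmp_path):
    config, result = toy_run
    rerun_cfg = RunConfig(config.pdb_path, "A", "B", "B",
                          output_dir=str(tmp_path / "out2"), make_figures=False)
    rerun = run_pipeline(rerun_cfg)
    for name in ("interface.csv", "scores.csv", "outliers.csv", "designer_set.csv",
                 "heatmap.csv", "per_position.csv", "boxplot_stats.json",
                 "summary.json", "mutation_list.txt"):
        a = (result.output_dir / name).read_bytes()
        b = (rerun.output_dir / name).read_bytes()
        if name == "summary.json":  # paths and figure flag differ; compare counts
            ja, jb = json.loads(a), json.loads(b)
            ja["parameters"].pop("pdb_path"), jb["parameters"].pop("pdb_path")
            assert ja == jb
        else:
            assert a == b, name


def test_summary_recomputable_from_emitted_tables(toy_run):
    _, result = toy_run
    out = result.output_dir
    summary = json.loads((out / "summary.json").read_text())
    interface = pd.read_csv(out / "interface.csv")
    scores = pd.read_csv(out / "scores.csv")
    outliers = pd.read_csv(out / "outliers.csv") if (out / "outliers.csv").stat().st_size > 1 else pd.DataFrame()
    designer = pd.read_csv(out / "designer_set.csv")
    assert summary["n_interface_residues"] == len(interface)
    assert summary["n_mutations_scanned"] == len(scores)
    assert summary["n_failed"] == int((scores.status != "ok").sum())
    n_enr = int((outliers.label == "enriching").sum()) if len(outliers) else 0
    n_dep = int((outliers.label == "depleting").sum()) if len(outliers) else 0
    assert summary["n_enriching_outliers"] == n_enr
    assert summary["n_depleting_outliers"] == n_dep
    kept = designer[designer.kept.astype(bool)]
    assert summary["n_enriching_final"] == int((kept.label == "enriching").sum())
    assert summary["n_depleting_final"] == int((kept.label == "depleting").sum())


def test_figures_written(toy_run):
    _, result = toy_run
    for name in ("heatmap.png", "boxplot.png", "per_position.png"):
        assert (result.output_dir / name).stat().st_size > 0


def test_planted_outlier_failing_stability_tracked(tmp_path):
    """An enriching outlier with destabilizing score shows up in the
    outliers table but not the final designer set, with provenance."""
    s, _ = make_toy_dimer(ToyDimerSpec(6, 3, 4.5, "LFAKED", "WYR"))
    pdb = tmp_path / "toy.pdb"
    pdb.write_text(write_pdb(s))

    from proton_scan import InterfaceParams, detect_interface, enumerate_mutations
    specs = enumerate_mutations(detect_interface(s, InterfaceParams("B", 5.0)))
    rng = np.random.default_rng(3)
    rows = ["mutation,ddg_bind,stability"]
    target = specs[5].code
    for sp in specs:
        if sp.code == target:
            rows.append(f"{sp.code},-60.0,2.5")  # huge enricher, bad stability
        else:
            rows.append(f"{sp.code},{rng.normal():.4f},-1.0")
    table = tmp_path / "scores_in.csv"
    table.write_text("\n".join(rows) + "\n")

    config = RunConfig(str(pdb), "A", "B", "B", backend=f"csv:{table}",
                       output_dir=str(tmp_path / "out"), make_figures=False)
    result = run_pipeline(config)
    out = result.output_dir
    outliers = pd.read_csv(out / "outliers.csv")
    assert target in set(outliers.mutation)
    designer = pd.read_csv(out / "designer_set.csv").set_index("mutation")
    assert not designer.loc[target, "passed_stability"]
    assert not designer.loc[target, "kept"]


def test_mutant_models_written_on_request(tmp_path):
    from proton_scan import parse_pdb

    s, _ = make_toy_dimer(ToyDimerSpec(4, 2, 4.5, "LFAK", "WY"))
    pdb = tmp_path / "toy.pdb"
    pdb.write_text(write_pdb(s))
    result = run_pipeline(RunConfig(str(pdb), "A", "B", "B",
                                    output_dir=str(tmp_path / "out"),
                                    make_figures=False, write_mutant_models=True))
    models = sorted((result.output_dir / "mutant_models").glob("*.pdb"))
    assert len(models) == result.summary.n_mutations_scanned
    reparsed = parse_pdb(models[0].read_text(), "A", "B")
    assert len(reparsed.residues) == 6


def test_invalid_config_rejected(tmp_path):
    with pytest.raises(ValueError):
        RunConfig("x.pdb", "A", "B", "C")


def test_cli_end_to_end_and_validation(tmp_path):
    from click.testing import CliRunner
    from proton_scan.cli import main

    s, _ = make_toy_dimer(ToyDimerSpec(6, 3, 4.5, "LFAKED", "WYR"))
    pdb = tmp_path / "toy.pdb"
    pdb.write_text(write_pdb(s))
    runner = CliRunner()

    ok = runner.invoke(main, ["run", "--pdb", str(pdb), "--chain-a", "A",
                              "--chain-b", "B", "--analyze", "B",
                              "--out", str(tmp_path / "cli_out"), "--no-figures"])
    assert ok.exit_code == 0, ok.output
    assert "mutations scanned:  57" in ok.output

    bad_cutoff = runner.invoke(main, ["run", "--pdb", str(pdb), "--chain-a", "A",
                                      "--chain-b", "B", "--analyze", "B",
                                      "--cutoff", "9.5"])
    assert bad_cutoff.exit_code != 0
    bad_iqr = runner.invoke(main, ["run", "--pdb", str(pdb), "--chain-a", "A",
                                   "--chain-b", "B", "--analyze", "B",
                                   "--iqr", "3.0"])
    assert bad_iqr.exit_code != 0

    iface = runner.invoke(main, ["interface", "--pdb", str(pdb), "--chain-a", "A",
                                 "--chain-b", "B", "--analyze", "B"])
    assert iface.exit_code == 0 and "W1" in iface.output

    scores_csv = tmp_path / "landscape.csv"
    scores = make_synthetic_landscape(LandscapeSpec(n_positions=8, seed=2,
                                                    planted=((4, "W", 60.0),)))
    rows = ["mutation,ddg_bind,stability"] + [
        f"{x.mutation.code},{x.ddg_bind:.5f},{x.stability:.5f}" for x in scores]
    scores_csv.write_text("\n".join(rows) + "\n")
    cls = runner.invoke(main, ["classify", "--scores", str(scores_csv)])
    assert cls.exit_code == 0, cls.output
    n_dep = int([l for l in cls.output.splitlines()
                 if l.startswith("n_depleting:")][0].split(":")[1])
    assert n_dep >= 1  # at least the planted extreme
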