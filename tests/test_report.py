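import hashlib
import json
from pathlib import Path

import pandas as pd
import pytest
from click.testing import CliRunner

from crosspep import io as cio
from crosspep.cli import main
from crosspep.report import OverlapReport, PipelineError, RunConfig, overlap_report, run_pipeline


def _panel(sequences, regulation="up"):
    return pd.DataFrame(
        {
            "sequence": sequences,
            "protein_name": ["COL1A1"] * len(sequences),
            "start": [1] * len(sequences),
            "stop": [len(s) for s in sequences],
            "p_adjusted": [0.01] * len(sequences),
            "mean_amp_case": [200.0] * len(sequences),
            "mean_amp_control": [100.0] * len(sequences),
            "regulation": [regulation] * len(sequences),
        }
    )


class TestOverlap:
    def test_identical_panels(self):
        p = _panel(["AAA", "BBB"])
        rep = overlap_report(p, p)
        assert rep.n_shared == 2 and rep.pct_early_shared == 100.0

    def test_disjoint_panels(self):
        rep = overlap_report(_panel(["AAA"]), _panel(["BBB"]))
        assert rep.n_shared == 0

    def test_constructed_counts(self):
        early = _panel(["A", "B", "C", "D", "E"])
        late = _panel(["A", "B", "C", "X", "Y", "Z", "W", "V"])
        rep = overlap_report(early, late)
        assert (rep.n_early, rep.n_late, rep.n_shared) == (5, 8, 3)
        assert rep.pct_early_shared == pytest.approx(60.0)

    def test_modification_sensitivity(self):
        early = _panel(["SpGSpGP"])
        late = _panel(["SPGSPGP"])
        assert overlap_report(early, late).n_shared == 0
        assert (
            overlap_report(early, late, modification_sensitive=False).n_shared == 1
        )


@pytest.fixture(scope="module")
def study_dir(tmp_path_factory, small_study):
    d = tmp_path_factory.mktemp("study")
    small_study.write(d)
    return d


def _write_run_config(study_dir, out_dir, path):
    import yaml

    peaks = str(study_dir / "rat_peaks.tsv")
    data = {
        "output_dir": str(out_dir),
        "peak_lists": [peaks],
        "group_map": str(study_dir / "rat_groups.tsv"),
        "standard_masses": [1046.54, 2191.07, 3016.49],
        "rat_panel": str(study_dir / "rat_panel.tsv"),
        "human_panel": str(study_dir / "human_panel.tsv"),
        "rat_fasta": str(study_dir / "rat_proteins.fasta"),
        "human_fasta": str(study_dir / "human_proteins.fasta"),
        "ortholog_map": str(study_dir / "ortholog_map.tsv"),
        "protein_filter": "COLSIM00",
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh)
    return data


class TestRunPipeline:
    def test_smoke_all_stages_in_manifest(self, study_dir, tmp_path):
        cfg_path = tmp_path / "run.yaml"
        _write_run_config(study_dir, tmp_path / "out", cfg_path)
        config = RunConfig.from_yaml(cfg_path)
        manifest = run_pipeline(config)
        assert set(manifest["stages"]) == {
            "featmatch", "markers", "seqqc", "orthology", "proteases",
        }
        assert not any(
            info.get("skipped") for info in manifest["stages"].values()
        )
        out = tmp_path / "out"
        for name in (
            "consensus_matrix.tsv", "marker_results.tsv", "qc_report.tsv",
            "orthology_matches.tsv", "protease_tallies.tsv", "manifest.json",
        ):
            assert (out / name).exists()

    def test_manifest_counts_consistent(self, study_dir, tmp_path):
        cfg_path = tmp_path / "run.yaml"
        _write_run_config(study_dir, tmp_path / "out", cfg_path)
        manifest = run_pipeline(RunConfig.from_yaml(cfg_path))
        stages = manifest["stages"]
        assert (
            stages["markers"]["n_tested"]
            <= stages["markers"]["n_after_frequency_filter"]
            <= stages["featmatch"]["n_consensus_peptides"]
        )
        assert stages["seqqc"]["n_mapped"] <= stages["seqqc"]["n_markers"]

    def test_rerun_byte_identical(self, study_dir, tmp_path):
        hashes = []
        for sub in ("out1", "out2"):
            cfg_path = tmp_path / f"{sub}.yaml"
            _write_run_config(study_dir, tmp_path / sub, cfg_path)
            run_pipeline(RunConfig.from_yaml(cfg_path))
            hashes.append(
                {
                    p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                    for p in sorted((tmp_path / sub).iterdir())
                }
            )
        assert hashes[0] == hashes[1]

    def test_outputs_reparse_round_trip(self, study_dir, tmp_path):
        cfg_path = tmp_path / "run.yaml"
        _write_run_config(study_dir, tmp_path / "out", cfg_path)
        run_pipeline(RunConfig.from_yaml(cfg_path))
        out = tmp_path / "out"
        peptides = cio.read_consensus_matrix(out / "consensus_matrix.tsv")
        assert peptides and all(p.amplitudes for p in peptides)
        markers = pd.read_csv(out / "marker_results.tsv", sep="\t")
        assert {"cluster_id", "p_adjusted", "regulation"}.issubset(markers.columns)
        with open(out / "manifest.json") as fh:
            json.load(fh)

    def test_missing_fasta_is_config_error(self, study_dir, tmp_path):
        with pytest.raises(FileNotFoundError, match="rat_fasta"):
            RunConfig(
                output_dir=str(tmp_path),
                rat_fasta=str(tmp_path / "nope.fasta"),
            )

    def test_stage_error_labeled_and_partial_retained(self, study_dir, tmp_path):
        # a peak list with a corrupt schema fails the featmatch stage
        bad = tmp_path / "bad_peaks.tsv"
        bad.write_text("sample_id\tmass_da\nx\tnot_a_number\n")
        config = RunConfig(
            output_dir=str(tmp_path / "out"),
            peak_lists=[str(bad)],
            group_map=str(study_dir / "rat_groups.tsv"),
        )
        with pytest.raises(PipelineError, match="featmatch"):
            run_pipeline(config)


class TestCLI:
    def test_simulate_and_report(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "study"
        result = runner.invoke(
            main, ["simulate", "--seed", "4", "--out", str(out)]
        )
        assert result.exit_code == 0, result.output
        assert (out / "rat_panel.tsv").exists()
        result = runner.invoke(
            main,
            [
                "report",
                "--early", str(out / "rat_panel.tsv"),
                "--late", str(out / "rat_panel.tsv"),
            ],
        )
        assert result.exit_code == 0
        assert "100.0% of early" in result.output

    def test_cluster_markers_chain(self, study_dir, tmp_path):
        runner = CliRunner()
        consensus = tmp_path / "consensus.tsv"
        result = runner.invoke(
            main,
            [
                "cluster",
                "--peaks", str(study_dir / "rat_peaks.tsv"),
                "--groups", str(study_dir / "rat_groups.tsv"),
                "--standards", "1046.54,2191.07,3016.49",
                "--out", str(consensus),
            ],
        )
        assert result.exit_code == 0, result.output
        out = tmp_path / "markers.tsv"
        result = runner.invoke(
            main,
            [
                "markers",
                "--consensus", str(consensus),
                "--groups", str(study_dir / "rat_groups.tsv"),
                "--out", str(out),
            ],
        )
        assert result.exit_code == 0, result.output
        assert "significant" in result.output

    def test_proteases_command(self, study_dir, tmp_path):
        runner = CliRunner()
        out = tmp_path / "tallies.tsv"
        result = runner.invoke(
            main,
            [
                "proteases",
                "--panel", str(study_dir / "rat_panel.tsv"),
                "--fasta", str(study_dir / "rat_proteins.fasta"),
                "--out", str(out),
            ],
        )
        assert result.exit_code == 0, result.output
        assert out.exists()

    def test_qc_command(self, study_dir, tmp_path):
        runner = CliRunner()
        out = tmp_path / "qc.tsv"
        result = runner.invoke(
            main,
            [
                "qc",
                "--panel", str(study_dir / "rat_panel.tsv"),
                "--fasta", str(study_dir / "rat_proteins.fasta"),
                "--out", str(out),
            ],
        )
        assert result.exit_code == 0, result.output
        qc = pd.read_csv(out, sep="\t")
        assert qc["passed"].all()

    def test_orthology_command(self, study_dir, tmp_path):
        runner = CliRunner()
        out = tmp_path / "matches.tsv"
        result = runner.invoke(
            main,
            [
                "orthology",
                "--rat-panel", str(study_dir / "rat_panel.tsv"),
                "--human-panel", str(study_dir / "human_panel.tsv"),
                "--rat-fasta", str(study_dir / "rat_proteins.fasta"),
                "--human-fasta", str(study_dir / "human_proteins.fasta"),
                "--ortholog-map", str(study_dir / "ortholog_map.tsv"),
                "--out", str(out),
            ],
        )
        assert result.exit_code == 0, result.output
        assert "tier counts" in result.output
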