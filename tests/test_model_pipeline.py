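"""Model/Results front end, YAML pipeline, and the CLI."""

import json

import numpy as np
import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

from rankloop import AnalysisConfig, DominanceModel
from rankloop.cli import main as cli_main
from rankloop.config import load_config, stage_seed
from rankloop.pipeline import PipelineError, run_analysis
from rankloop.synth import GeneratorConfig, simulate_events


@pytest.fixture(scope="module")
def small_log():
    log, _ = simulate_events(GeneratorConfig(n_individuals=10, total_events=500,
                                             rng_seed=21))
    return log


FAST = dict(null_replicates=40, max_chain_length=3, rng_seed=5)


class TestModel:
    def test_fit_produces_windows_and_summary(self, small_log):
        res = DominanceModel(small_log, AnalysisConfig(**FAST)).fit()
        assert [w.label for w in res.windows] == ["Q1", "Q2", "Q3", "Q4"]
        text = res.summary()
        assert "ratio" in text and "Q4" in text
        assert set(res.scores_frame()["method"]) == {"EC", "WSC", "DS"}

    def test_refit_is_deterministic(self, small_log):
        cfg = AnalysisConfig(**FAST)
        a = DominanceModel(small_log, cfg).fit()
        b = DominanceModel(small_log, cfg).fit()
        pd.testing.assert_frame_equal(a.chains_frame(), b.chains_frame())
        pd.testing.assert_frame_equal(a.profile_frame(), b.profile_frame())

    def test_exclusion_propagates_to_all_outputs(self, small_log):
        drop = small_log.roster[0]
        cfg = AnalysisConfig(excluded_ids=(drop,), **FAST)
        res = DominanceModel(small_log, cfg).fit()
        assert res.whole.matrix.n == small_log.n_individuals - 1
        assert drop not in res.scores_frame()["id"].values
        # profile Delta range shrinks with the roster
        assert res.whole.profile.deltas.max() == small_log.n_individuals - 2

    def test_bootstrap_stage_attaches_uncertainty(self, small_log):
        cfg = AnalysisConfig(bootstrap_replicates=15, **FAST)
        res = DominanceModel(small_log, cfg).fit()
        assert res.whole.boot_power is not None
        assert "boot_sd" in res.scores_frame().columns

    def test_save_writes_csvs_and_manifest(self, small_log, tmp_path):
        res = DominanceModel(small_log, AnalysisConfig(**FAST)).fit()
        manifest = res.save(tmp_path)
        for f in ("scores.csv", "profiles.csv", "chains.csv", "ratios.csv",
                  "manifest.json"):
            assert (tmp_path / f).exists()
        assert manifest["config"]["rng_seed"] == 5


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("cooldown_seconds: 30\nexcluded_ids: [NBB]\nrng_seed: 3\n")
        cfg = load_config(p)
        assert cfg.cooldown_seconds == 30
        assert cfg.excluded_ids == ("NBB",)

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("coolddown: 30\n")
        with pytest.raises(ValueError, match="unknown config keys"):
            load_config(p)

    def test_stage_seeds_stable_and_distinct(self):
        assert stage_seed(1, "null:Q1") == stage_seed(1, "null:Q1")
        assert stage_seed(1, "null:Q1") != stage_seed(1, "null:Q2")
        assert 0 <= stage_seed(123456, "x") < 2**31


class TestPipeline:
    def _run_cfg(self, tmp_path, **extra):
        cfg = {
            "output_dir": str(tmp_path / "out"),
            "simulate": {"n_individuals": 8, "total_events": 300, "rng_seed": 2},
            "analysis": {"null_replicates": 30, "max_chain_length": 2,
                         "rng_seed": 1},
        }
        cfg.update(extra)
        p = tmp_path / "run.yaml"
        p.write_text(yaml.safe_dump(cfg))
        return p

    def test_full_run_writes_outputs_and_manifest(self, tmp_path):
        manifest = run_analysis(self._run_cfg(tmp_path))
        out = tmp_path / "out"
        for f in ("scores.csv", "profiles.csv", "chains.csv", "manifest.json"):
            assert (out / f).exists()
        assert "analysis" in manifest["stage_seconds"]
        assert manifest["stage_seeds"]  # seeds recorded for reproducibility

    def test_rerun_is_numerically_identical(self, tmp_path):
        p = self._run_cfg(tmp_path)
        run_analysis(p, output_dir=tmp_path / "a")
        run_analysis(p, output_dir=tmp_path / "b")
        for f in ("scores.csv", "profiles.csv", "chains.csv"):
            assert (tmp_path / "a" / f).read_text() == (tmp_path / "b" / f).read_text()

    def test_failure_names_the_stage(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text(yaml.safe_dump({"events_csv": str(tmp_path / "missing.csv")}))
        with pytest.raises(PipelineError, match="ingest"):
            run_analysis(p, output_dir=tmp_path / "out")
        # partial manifest still written
        assert json.loads((tmp_path / "out" / "manifest.json").read_text())[
            "failed_stage"] == "ingest"


class TestDemo:
    def test_demo_contrast_and_digest_determinism(self, tmp_path):
        from rankloop.pipeline import make_demo

        rep1 = make_demo(seed=0, outdir=tmp_path / "d1")
        rep2 = make_demo(seed=0, outdir=tmp_path / "d2")
        assert rep1["digests"] == rep2["digests"]  # golden regression surface
        ratios = {}
        for name, man in rep1["groups"].items():
            df = pd.read_csv(tmp_path / "d1" / name / "out" / "ratios.csv")
            ratios[name] = df.set_index("window").loc["all", "above_null_ratio"]
        assert ratios["structured"] > ratios["unstructured"]
        assert make_demo(seed=1, outdir=tmp_path / "d3")["digests"] != rep1["digests"]


class TestCli:
    def test_simulate_then_run(self, tmp_path):
        runner = CliRunner()
        r = runner.invoke(cli_main, ["simulate", "--out", str(tmp_path / "sim"),
                                     "--seed", "3", "--scans", "40"])
        assert r.exit_code == 0, r.output
        truth = json.loads((tmp_path / "sim" / "ground_truth.json").read_text())
        assert len(truth["latent_ranks"]) == 20

        cfg = {
            "output_dir": str(tmp_path / "out"),
            "events_csv": str(tmp_path / "sim" / "events.csv"),
            "scans_csv": str(tmp_path / "sim" / "scans.csv"),
            "analysis": {"null_replicates": 25, "max_chain_length": 2,
                         "rng_seed": 2},
        }
        p = tmp_path / "run.yaml"
        p.write_text(yaml.safe_dump(cfg))
        r = runner.invoke(cli_main, ["run", "--config", str(p)])
        assert r.exit_code == 0, r.output
        assert "ratio" in r.output
        cov = pd.read_csv(tmp_path / "out" / "covariates.csv")
        assert "nearest_neighbor" in cov["signal"].values
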