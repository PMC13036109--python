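"""Benchmark harness, file round-trips, CLI and pipeline smoke tests."""

import numpy as np
import pandas as pd
import pytest

from cytomod import (BenchmarkConfig, ModelConfig, SimulationConfig,
                     generate_cohort, run_benchmark, summarize, write_report)
from cytomod import io as cio
from cytomod.bench import FullyConnectedNet
from cytomod.graph import ModulePartition


@pytest.fixture(scope="module")
def tiny_bench_results():
    sim = SimulationConfig(n_genes=100, n_modules=5, n_deg_up=4, n_deg_down=4,
                           n_ra=60, n_control=30,
                           mu_up_range=(1.5, 2.5), mu_down_range=(-2.5, -1.5),
                           seed=0)
    cfg = BenchmarkConfig(
        roster=("logistic_regression", "naive_bayes"), n_runs=2, base_seed=0,
        sim_config=sim, graph_fraction=0.05,
        model_config=ModelConfig(max_epochs=5),
    )
    return run_benchmark(cfg)


class TestBenchmark:
    def test_row_layout(self, tiny_bench_results):
        assert len(tiny_bench_results) == 4  # 2 models x 2 runs
        assert set(tiny_bench_results["model"]) == {"logistic_regression",
                                                    "naive_bayes"}

    def test_separable_toy_all_models_near_perfect(self, tiny_bench_results):
        assert (tiny_bench_results["auc"] > 0.9).all()

    def test_summary_mean_and_sd(self, tiny_bench_results):
        s = summarize(tiny_bench_results).set_index("model")
        lr = tiny_bench_results[tiny_bench_results["model"] == "logistic_regression"]
        assert s.loc["logistic_regression", "auc_mean"] == pytest.approx(
            lr["auc"].mean(), abs=1e-12)
        assert s.loc["logistic_regression", "auc_std"] == pytest.approx(
            lr["auc"].std(ddof=1), abs=1e-12)

    def test_determinism(self):
        sim = SimulationConfig(n_genes=60, n_modules=3, n_deg_up=3, n_deg_down=3,
                               n_ra=40, n_control=20,
                               mu_up_range=(1.5, 2.5), mu_down_range=(-2.5, -1.5),
                               seed=0)
        cfg = BenchmarkConfig(roster=("logistic_regression",), n_runs=2,
                              base_seed=4, sim_config=sim, graph_fraction=0.1)
        a = run_benchmark(cfg)
        b = run_benchmark(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_report_round_trip(self, tiny_bench_results, tmp_path):
        path = tmp_path / "table3.csv"
        pretty = write_report(tiny_bench_results, str(path))
        re_read = pd.read_csv(path)
        pd.testing.assert_frame_equal(
            re_read, tiny_bench_results.reset_index(drop=True),
            check_exact=False, atol=1e-12)
        assert (tmp_path / "table3_summary.csv").exists()
        # 3-decimal formatting rule
        assert pretty["auc"].str.match(r"\d\.\d{3} ± \d\.\d{3}").all()

    def test_formatting_rounds_half_up_like_printf(self):
        assert f"{0.9615:.3f}" == "0.962"

    def test_fcnn_learns_separable_toy(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(200, 30)).astype(np.float32)
        y = (x[:, 0] + x[:, 1] > 0).astype(int)
        net = FullyConnectedNet(max_epochs=80, seed=0).fit(x[:150], y[:150])
        from sklearn.metrics import roc_auc_score
        assert roc_auc_score(y[150:], net.predict_proba_matrix(x[150:])) > 0.85


class TestLeakageGuard:
    def test_leaky_scaler_inflates_separable_auc(self):
        """Fitting the scaler on all data leaks test statistics: AUC rises."""
        from sklearn.linear_model import LogisticRegression
        from sklearn.metrics import roc_auc_score

        from cytomod import stratified_split, zscore_normalize
        rng_scores = {"honest": [], "leaky": []}
        for seed in range(3):
            cfg = SimulationConfig(n_genes=300, n_modules=5, n_deg_up=2,
                                   n_deg_down=2, n_ra=30, n_control=30,
                                   mu_up_range=(0.5, 0.8),
                                   mu_down_range=(-0.8, -0.5), seed=seed)
            cohort = generate_cohort(cfg)
            split = stratified_split(cohort, seed=seed)
            honest_tr = zscore_normalize(split.train)
            honest_te = zscore_normalize(split.test, reference=split.train)
            # leak: scaler fitted on train+test pooled
            pooled = zscore_normalize(cohort)
            leak_tr = pooled.subset(np.flatnonzero(np.isin(
                cohort.sample_ids, split.train.sample_ids)))
            leak_te = pooled.subset(np.flatnonzero(np.isin(
                cohort.sample_ids, split.test.sample_ids)))
            for tag, tr, te in [("honest", honest_tr, honest_te),
                                ("leaky", leak_tr, leak_te)]:
                clf = LogisticRegression(max_iter=1000).fit(tr.expression, tr.labels)
                rng_scores[tag].append(roc_auc_score(
                    te.labels, clf.predict_proba(te.expression)[:, 1]))
        # leakage through pooled normalisation must not *reduce* measured AUC
        assert np.mean(rng_scores["leaky"]) >= np.mean(rng_scores["honest"]) - 0.02


class TestIO:
    def test_expression_round_trip_bit_equal(self, toy_cohort, tmp_path):
        path = tmp_path / "expr.tsv"
        cio.write_expression(toy_cohort, path)
        back = cio.read_expression(path)
        assert np.array_equal(back.expression, toy_cohort.expression)
        assert list(back.gene_ids) == list(toy_cohort.gene_ids)

    def test_labels_and_metadata_join(self, toy_cohort, tmp_path):
        cio.write_expression(toy_cohort, tmp_path / "e.tsv")
        cio.write_labels(toy_cohort, tmp_path / "l.tsv")
        cio.write_gene_metadata(toy_cohort, tmp_path / "g.tsv")
        back = cio.read_expression(tmp_path / "e.tsv", tmp_path / "l.tsv",
                                   tmp_path / "g.tsv")
        assert np.array_equal(back.labels, toy_cohort.labels)
        assert np.array_equal(back.deg_effect, toy_cohort.deg_effect)
        assert np.array_equal(back.true_module_of_gene,
                              toy_cohort.true_module_of_gene)

    def test_hand_written_matrix(self, tmp_path):
        path = tmp_path / "hand.tsv"
        path.write_text("sample_id\tg1\tg2\tg3\tg4\n"
                        "s1\t1.5\t2\t-3\t0\n"
                        "s2\t0.25\t-1\t4.5\t1e-3\n"
                        "s3\t7\t8\t9\t10\n")
        cohort = cio.read_expression(path)
        assert cohort.expression.shape == (3, 4)
        assert cohort.expression[1, 3] == 1e-3
        assert cohort.expression[0, 2] == -3

    def test_duplicate_gene_header_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("sample_id\tg1\tg1\ns1\t1\t2\n")
        with pytest.raises(cio.ParseError, match="g1"):
            cio.read_expression(path)

    def test_non_numeric_cell_named(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("sample_id\tg1\tg2\ns1\t1\txyz\n")
        with pytest.raises(cio.ParseError, match="g2"):
            cio.read_expression(path)

    def test_graph_round_trip(self, toy_graph, toy_cohort, tmp_path):
        path = tmp_path / "graph.tsv"
        cio.write_graph(toy_graph, toy_cohort.gene_ids, path)
        back = cio.read_graph(path, toy_cohort.gene_ids)
        assert np.array_equal(back.edge_a, toy_graph.edge_a)
        assert np.array_equal(back.edge_b, toy_graph.edge_b)
        assert np.allclose(back.r, toy_graph.r)
        assert np.allclose(back.weight, toy_graph.weight)
        assert back.gamma == toy_graph.gamma

    def test_partition_round_trip(self, toy_partition, toy_cohort, tmp_path):
        path = tmp_path / "part.tsv"
        cio.write_partition(toy_partition, toy_cohort.gene_ids, path)
        back = cio.read_partition(path, toy_cohort.gene_ids)
        assert np.array_equal(back.module_of_gene, toy_partition.module_of_gene)

    def test_manifest_written_with_digests(self, toy_cohort, tmp_path):
        import json
        cio.write_expression(toy_cohort, tmp_path / "e.tsv")
        mpath = cio.write_manifest(tmp_path, "simulate", {"seed": 1}, 1,
                                   {}, {"expr": str(tmp_path / "e.tsv")})
        manifest = json.loads(open(mpath).read())
        assert manifest["outputs"]["expr"] == cio.file_digest(tmp_path / "e.tsv")
        assert manifest["master_seed"] == 1


@pytest.fixture(scope="module")
def pipeline_run(tmp_path_factory):
    from cytomod.pipeline import default_config, run_pipeline
    out = tmp_path_factory.mktemp("run")
    cfg = default_config(scale="reduced", seed=0)
    cfg["simulate"] = SimulationConfig(
        n_genes=120, n_modules=6, n_deg_up=5, n_deg_down=5,
        n_ra=60, n_control=30, mu_up_range=(1.0, 2.0),
        mu_down_range=(-2.0, -1.0), seed=0).__dict__ | {
        "holdout_n_ra": 10, "holdout_n_control": 5}
    cfg["graph"] = {"fraction": 0.05, "gamma": 4.0}
    cfg["model"] = ModelConfig(max_epochs=5, early_stop_patience=3).__dict__
    cfg["explain"] = {"n_background": 8, "n_explain": 2, "n_permutations": 2}
    cfg["benchmark"] = {}
    summary = run_pipeline(cfg, str(out))
    return out, cfg, summary


class TestPipelineAndCLI:
    def test_pipeline_emits_all_artifacts(self, pipeline_run):
        out, _, summary = pipeline_run
        for f in ["train.tsv", "test.tsv", "holdout.tsv", "graph.tsv",
                  "modules.tsv", "model.npz", "metrics.csv",
                  "perturbation_screen.csv", "gene_importance.csv",
                  "module_contribution.csv", "summary.json"]:
            assert (out / f).exists(), f
        assert 0 <= summary["test_metrics"]["auc"] <= 1

    def test_pipeline_resume_skips_simulation(self, pipeline_run):
        from cytomod.pipeline import run_pipeline
        out, cfg, _ = pipeline_run
        before = (out / "train.tsv").stat().st_mtime
        run_pipeline(cfg, str(out))
        assert (out / "train.tsv").stat().st_mtime == before

    def test_cli_simulate_and_graph(self, tmp_path):
        from click.testing import CliRunner
        from cytomod.cli import main
        runner = CliRunner()
        out = tmp_path / "sim"
        config = tmp_path / "cfg.yaml"
        config.write_text(
            "simulate:\n  n_genes: 60\n  n_modules: 3\n  n_deg_up: 2\n"
            "  n_deg_down: 2\n  n_ra: 30\n  n_control: 15\n")
        res = runner.invoke(main, ["simulate", "--config", str(config),
                                   "--seed", "1", "--out", str(out)])
        assert res.exit_code == 0, res.output
        assert (out / "train.tsv").exists()
        res = runner.invoke(main, ["build-graph", "--expression",
                                   str(out / "train.tsv"), "--fraction", "0.1",
                                   "--out", str(out / "graph.tsv")])
        assert res.exit_code == 0, res.output
        assert (out / "graph_modules.tsv").exists()
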