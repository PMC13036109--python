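"""End-to-end orchestration: simulate -> normalise/split -> graph -> train ->
evaluate -> perturbation screen -> attribution -> report.

Each stage writes its outputs plus a manifest into the run directory; a
re-run skips stages whose outputs exist and whose manifest config hash
matches, so deleting one intermediate file re-runs only that stage and the
stages after it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from ._rng import substream_seed
from .bench import BenchmarkConfig, reduced_profile, run_benchmark, write_report
from .graph import build_graph, louvain_partition, recovery_metrics
from .interpret import gene_importance, module_contribution
from .model import (ModelConfig, evaluate_metrics, load_model, predict_proba,
                    save_model, train_model)
from .perturb import perturbation_screen
from .simulate import (SimulationConfig, TABLE_SPLIT_COUNTS, generate_cohort,
                       generate_holdout, stratified_split, zscore_normalize)

logger = logging.getLogger(__name__)

STAGE_ORDER = ("simulate", "graph", "train", "evaluate", "perturb", "explain", "benchmark")


def default_config(scale: str = "reduced", seed: int = 0) -> dict:
    sim = SimulationConfig(seed=seed) if scale == "full" else reduced_profile(seed=seed)
    return {
        "scale": scale,
        "seed": seed,
        "simulate": sim.__dict__ | {"holdout_n_ra": 100, "holdout_n_control": 50},
        "graph": {"fraction": 0.01, "gamma": 4.0},
        "model": ModelConfig().__dict__,
        "perturb": {"delta": 0.2},
        "explain": {"n_background": 32, "n_explain": 8, "n_permutations": 16},
        "benchmark": {"roster": ["logistic_regression", "xgboost", "fcnn",
                                 "full", "vae_only", "gat_only"], "n_runs": 2},
    }


def _section_hash(section: dict) -> str:
    return hashlib.sha256(json.dumps(section, sort_keys=True, default=str).encode()
                          ).hexdigest()[:16]


def _stage_fresh(out: Path, stage: str, section: dict, files: list[str]) -> bool:
    manifest = out / f"manifest_{stage}.json"
    if not manifest.exists() or not all((out / f).exists() for f in files):
        return False
    recorded = json.loads(manifest.read_text()).get("config_hash")
    return recorded == _section_hash(section)


def run_pipeline(config: dict, out_dir: str, resume: bool = True) -> dict:
    """Execute (or resume) the whole workflow; returns a summary dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    summary: dict = {}
    upstream_reran = False

    # ---- simulate ----------------------------------------------------- #
    sim_section = dict(config["simulate"])
    holdout_n = (sim_section.pop("holdout_n_ra", 100), sim_section.pop("holdout_n_control", 50))
    sim_cfg = SimulationConfig(**sim_section)
    sim_files = ["train.tsv", "test.tsv", "holdout.tsv", "train_labels.tsv",
                 "test_labels.tsv", "holdout_labels.tsv", "genes.tsv"]
    if not (resume and _stage_fresh(out, "simulate", sim_section, sim_files)):
        upstream_reran = True
        cohort = generate_cohort(sim_cfg)
        target = TABLE_SPLIT_COUNTS["train"] if (
            sim_cfg.n_ra == 240 and sim_cfg.n_control == 120) else None
        split = stratified_split(cohort, target_counts=target,
                                 seed=substream_seed(seed, "pipeline-split"))
        holdout = generate_holdout(sim_cfg, *holdout_n)
        cio.write_expression(split.train, out / "train.tsv")
        cio.write_expression(split.test, out / "test.tsv")
        cio.write_expression(holdout, out / "holdout.tsv")
        cio.write_labels(split.train, out / "train_labels.tsv")
        cio.write_labels(split.test, out / "test_labels.tsv")
        cio.write_labels(holdout, out / "holdout_labels.tsv")
        cio.write_gene_metadata(cohort, out / "genes.tsv")
        cio.write_manifest(out, "simulate", sim_section, seed,
                           {}, {f: str(out / f) for f in sim_files})
    train_c = cio.read_expression(out / "train.tsv", out / "train_labels.tsv",
                                  out / "genes.tsv")
    test_c = cio.read_expression(out / "test.tsv", out / "test_labels.tsv",
                                 out / "genes.tsv")
    summary["n_train"] = train_c.n_samples
    summary["n_test"] = test_c.n_samples

    train_z = zscore_normalize(train_c)
    test_z = zscore_normalize(test_c, reference=train_c)

    # ---- graph -------------------------------------------------------- #
    g_section = dict(config["graph"])
    g_files = ["graph.tsv", "modules.tsv"]
    if not (resume and not upstream_reran and _stage_fresh(out, "graph", g_section, g_files)):
        upstream_reran = True
        graph = build_graph(train_z, fraction=g_section["fraction"], gamma=g_section["gamma"])
        partition = louvain_partition(graph, seed=substream_seed(seed, "pipeline-louvain"))
        cio.write_graph(graph, train_c.gene_ids, out / "graph.tsv")
        cio.write_partition(partition, train_c.gene_ids, out / "modules.tsv")
        cio.write_manifest(out, "graph", g_section, seed,
                           {"train": str(out / "train.tsv")},
                           {f: str(out / f) for f in g_files})
    graph = cio.read_graph(out / "graph.tsv", train_c.gene_ids)
    partition = cio.read_partition(out / "modules.tsv", train_c.gene_ids)
    from .graph import ModulePartition
    truth = ModulePartition(train_c.true_module_of_gene, method="ground_truth")
    summary["module_recovery"] = recovery_metrics(partition, truth)

    # ---- train -------------------------------------------------------- #
    m_section = dict(config["model"])
    if not (resume and not upstream_reran
            and _stage_fresh(out, "train", m_section, ["model.npz"])):
        upstream_reran = True
        model_cfg = ModelConfig(**m_section)
        trained = train_model(train_z, graph, partition, model_cfg)
        save_model(trained, out / "model.npz")
        cio.write_manifest(out, "train", m_section, seed,
                           {"train": str(out / "train.tsv"), "graph": str(out / "graph.tsv")},
                           {"model": str(out / "model.npz")})
    trained = load_model(out / "model.npz")

    # ---- evaluate ----------------------------------------------------- #
    p = predict_proba(trained, test_z)
    metrics = evaluate_metrics(p, test_c.labels)
    summary["test_metrics"] = metrics
    pd.DataFrame([metrics]).to_csv(out / "metrics.csv", index=False)
    cio.write_manifest(out, "evaluate", m_section, seed,
                       {"model": str(out / "model.npz")},
                       {"metrics": str(out / "metrics.csv")})

    # ---- perturbation screen ------------------------------------------ #
    screen = perturbation_screen(trained, test_z, delta=config["perturb"]["delta"])
    screen.to_csv(out / "perturbation_screen.csv", index=False)
    summary["top_perturbation"] = screen.iloc[0].to_dict()

    # ---- attribution -------------------------------------------------- #
    ex = config["explain"]
    genes = gene_importance(trained, train_z, n_background=ex["n_background"],
                            n_explain=ex["n_explain"],
                            n_permutations=ex["n_permutations"],
                            seed=substream_seed(seed, "pipeline-shap"))
    genes.to_csv(out / "gene_importance.csv", index=False)
    modules = module_contribution(trained, test_z)
    modules.to_csv(out / "module_contribution.csv", index=False)
    summary["top_gene"] = str(genes.iloc[0]["entity_id"])
    summary["top_module"] = int(modules.iloc[0]["entity_id"])

    # ---- benchmark ---------------------------------------------------- #
    b_section = dict(config.get("benchmark") or {})
    if b_section:
        bc = BenchmarkConfig(
            roster=tuple(b_section.get("roster", ["logistic_regression", "full"])),
            n_runs=int(b_section.get("n_runs", 2)),
            base_seed=seed,
            sim_config=sim_cfg,
            model_config=ModelConfig(**m_section),
        )
        results = run_benchmark(bc)
        write_report(results, str(out / "table3.csv"))
        summary["benchmark_models"] = sorted(results["model"].unique().tolist())

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary
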