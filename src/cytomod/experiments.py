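"""Canned reproduction experiments at the package's two study scales.

These functions re-run the full workflow end to end — generate a cohort,
split it, refit scaler/graph/partition, train, score — and return plain
dictionaries of measurements.  They are what the reproduction script and
the acceptance tests execute; nothing here reads stored results.

Scales:

* **full** — the reference design: 15,000 genes, 100 modules of 150,
  300 DEGs, 360 samples.  Used for simulator bookkeeping, the graph/
  module census and the flat-matrix baselines, which run in seconds to
  minutes at this size.
* **reduced** — 600 genes, 20 modules of 30, 12 DEGs (DEG fraction,
  effect-size distribution, correlation structure and sample counts
  preserved).  Used for the network panels, whose graph-attention
  training is the dominant cost.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional

import numpy as np

from ._rng import substream_seed
from .bench import FullyConnectedNet, reduced_profile
from .graph import ModulePartition, build_graph, louvain_partition, recovery_metrics
from .model import (ModelConfig, cross_validate, evaluate_metrics,
                    predict_proba, train_model)
from .perturb import PerturbationSpec, perturb_module
from .simulate import (SimulationConfig, TABLE_SPLIT_COUNTS, generate_cohort,
                       stratified_split, zscore_normalize)

__all__ = [
    "simulator_census",
    "graph_module_census",
    "baseline_panel",
    "reduced_network_run",
    "reduced_network_panel",
    "reduced_cross_validation",
]

NETWORK_VARIANTS = ("full", "vae_only", "gat_only")


def simulator_census(seed: int = 0) -> dict:
    """Bookkeeping of the default design: cohort, split and holdout counts."""
    from .simulate import generate_holdout

    cfg = SimulationConfig(seed=seed)
    cohort = generate_cohort(cfg)
    split = stratified_split(cohort, target_counts=TABLE_SPLIT_COUNTS["train"],
                             seed=substream_seed(seed, "census-split"))
    holdout = generate_holdout(cfg, 100, 50)
    return {
        "n_samples": cohort.n_samples,
        "n_ra": int((cohort.labels == 1).sum()),
        "n_control": int((cohort.labels == 0).sum()),
        "n_genes": cohort.n_genes,
        "n_deg": int((cohort.deg_effect != 0).sum()),
        "train_counts": split.train.class_counts(),
        "test_counts": split.test.class_counts(),
        "n_train": split.train.n_samples,
        "n_test": split.test.n_samples,
        "holdout_counts": holdout.class_counts(),
        "n_holdout": holdout.n_samples,
    }


def graph_module_census(seed: int = 0, fraction: float = 0.01,
                        gamma: float = 4.0) -> dict:
    """Full-scale graph construction + Louvain census on the training split."""
    cfg = SimulationConfig(seed=seed)
    cohort = generate_cohort(cfg)
    split = stratified_split(cohort, target_counts=TABLE_SPLIT_COUNTS["train"],
                             seed=substream_seed(seed, "census-split"))
    train_z = zscore_normalize(split.train)
    graph = build_graph(train_z, fraction=fraction, gamma=gamma)
    partition = louvain_partition(graph, seed=substream_seed(seed, "census-louvain"))
    truth = ModulePartition(cohort.true_module_of_gene, method="ground_truth")
    out = recovery_metrics(partition, truth)
    out["n_edges"] = graph.n_edges
    out["n_genes"] = cohort.n_genes
    return out


def _split_and_normalize(cohort, seed: int):
    target = (TABLE_SPLIT_COUNTS["train"]
              if (cohort.class_counts().get(1), cohort.class_counts().get(0))
              == (240, 120) else None)
    split = stratified_split(cohort, target_counts=target,
                             seed=substream_seed(seed, "exp-split"))
    train_z = zscore_normalize(split.train)
    test_z = zscore_normalize(split.test, reference=split.train)
    return split, train_z, test_z


def baseline_panel(seed: int = 0, n_runs: int = 5,
                   models: tuple[str, ...] = ("logistic_regression", "xgboost",
                                              "fcnn")) -> dict:
    """Flat-matrix baselines on the full-scale design, averaged over runs.

    Each run regenerates the cohort (data seed) and refits each model
    (model seed); returns mean/sd test AUC and accuracy per model.
    """
    from .bench import _sklearn_baseline

    per_model: dict[str, list[dict]] = {m: [] for m in models}
    for run in range(n_runs):
        data_seed = substream_seed(seed, f"baseline-data-{run}")
        model_seed = substream_seed(seed, f"baseline-model-{run}")
        cohort = generate_cohort(SimulationConfig(seed=data_seed))
        _, train_z, test_z = _split_and_normalize(cohort, data_seed)
        for name in models:
            if name == "fcnn":
                est = FullyConnectedNet(seed=model_seed).fit(
                    train_z.expression.astype(np.float32), train_z.labels)
                p = est.predict_proba_matrix(test_z.expression.astype(np.float32))
            else:
                clf = _sklearn_baseline(name, model_seed).fit(
                    train_z.expression, train_z.labels)
                p = clf.predict_proba(test_z.expression)[:, 1]
            per_model[name].append(evaluate_metrics(p, test_z.labels))
    out = {}
    for name, rows in per_model.items():
        out[name] = {
            "auc_mean": float(np.mean([r["auc"] for r in rows])),
            "auc_sd": float(np.std([r["auc"] for r in rows], ddof=1)),
            "accuracy_mean": float(np.mean([r["accuracy"] for r in rows])),
            "runs": rows,
        }
    out["n_test"] = 108
    return out


def _designated_detected_modules(cohort, partition) -> dict[int, int]:
    """Map each designated ground-truth module to a detected module.

    Community detection may fragment a planted module; the perturbation
    target is the fragment that carries the module's differential signal,
    so the mapping follows the module's DEG genes (falling back to total
    gene overlap if the module holds no DEGs).
    """
    mapping = {}
    for truth_m in sorted(cohort.provenance.get("designated_modules", {0: None})):
        genes = np.flatnonzero(cohort.true_module_of_gene == truth_m)
        deg_genes = genes[cohort.deg_effect[genes] != 0]
        pool = deg_genes if deg_genes.size else genes
        counts = np.bincount(partition.module_of_gene[pool],
                             minlength=partition.n_modules)
        mapping[truth_m] = int(np.argmax(counts))
    return mapping


def reduced_network_run(
    run_seed: int,
    variants: tuple[str, ...] = NETWORK_VARIANTS,
    include_fcnn: bool = True,
    delta: float = 0.2,
    model_config: Optional[ModelConfig] = None,
    sim_config: Optional[SimulationConfig] = None,
) -> dict:
    """One complete reduced-scale run: all network variants + perturbations.

    Returns per-variant test metrics, and for the three designated
    cytokine-responsive modules the up/down mean Delta-p of the full model.
    """
    data_seed = substream_seed(run_seed, "reduced-data")
    model_seed = substream_seed(run_seed, "reduced-model")
    cfg = sim_config if sim_config is not None else reduced_profile(seed=data_seed)
    cfg = replace(cfg, seed=data_seed)
    cohort = generate_cohort(cfg)
    split, train_z, test_z = _split_and_normalize(cohort, data_seed)
    graph = build_graph(train_z, fraction=0.01, gamma=4.0)
    partition = louvain_partition(graph, seed=substream_seed(model_seed, "louvain"))

    base_mc = model_config if model_config is not None else ModelConfig()
    out: dict = {"metrics": {}, "perturbation": {}}
    trained_full = None
    for variant in variants:
        mc = replace(base_mc, variant=variant, seed=model_seed)
        trained = train_model(train_z, None if variant == "vae_only" else graph,
                              partition, mc)
        p = predict_proba(trained, test_z)
        out["metrics"][variant] = evaluate_metrics(p, test_z.labels)
        if variant == "full":
            trained_full = trained
    if include_fcnn:
        est = FullyConnectedNet(seed=model_seed).fit(
            train_z.expression.astype(np.float32), train_z.labels)
        p = est.predict_proba_matrix(test_z.expression.astype(np.float32))
        out["metrics"]["fcnn"] = evaluate_metrics(p, test_z.labels)

    if trained_full is not None:
        mapping = _designated_detected_modules(cohort, partition)
        for truth_m, detected in mapping.items():
            entry = {}
            for direction in ("up", "down"):
                res = perturb_module(trained_full, test_z, PerturbationSpec(
                    module_index=detected, direction=direction, delta=delta))
                entry[direction] = {"mean_delta_p": res.mean_delta_p,
                                    "sd_delta_p": res.sd_delta_p,
                                    "p_value": res.p_value}
            entry["detected_module"] = detected
            out["perturbation"][truth_m] = entry
    out["n_test"] = test_z.n_samples
    out["n_genes"] = cohort.n_genes
    return out


def reduced_network_panel(seed: int = 0, n_runs: int = 5, **kwargs) -> dict:
    """Seed-averaged reduced-scale panel: mean metrics per variant and the
    designated-module perturbation summary (means over runs; hierarchy
    agreement counted across runs)."""
    runs = [reduced_network_run(substream_seed(seed, f"panel-{r}"), **kwargs)
            for r in range(n_runs)]
    variants = runs[0]["metrics"].keys()
    out: dict = {"runs": runs, "mean": {}, "n_runs": n_runs}
    for v in variants:
        out["mean"][v] = {
            k: float(np.mean([r["metrics"][v][k] for r in runs]))
            for k in ("auc", "accuracy", "f1")
        }
        out["mean"][v]["auc_sd"] = float(np.std(
            [r["metrics"][v]["auc"] for r in runs], ddof=1))
    if runs[0]["perturbation"]:
        designated = sorted(runs[0]["perturbation"])
        pert = {}
        for m in designated:
            pert[m] = {
                d: float(np.mean([r["perturbation"][m][d]["mean_delta_p"]
                                  for r in runs]))
                for d in ("up", "down")
            }
        out["perturbation_mean"] = pert
        # hierarchy: designated modules ranked by |mean up-shift| per run
        agree = 0
        for r in runs:
            effects = [abs(r["perturbation"][m]["up"]["mean_delta_p"])
                       for m in designated]
            if all(effects[i] >= effects[i + 1] for i in range(len(effects) - 1)):
                agree += 1
        out["hierarchy_agreement"] = agree
    out["n_test"] = runs[0]["n_test"]
    return out


def reduced_cross_validation(seed: int = 0, k: int = 3,
                             model_config: Optional[ModelConfig] = None) -> dict:
    """Stratified k-fold CV of the full model on a reduced-scale cohort."""
    cfg = reduced_profile(seed=substream_seed(seed, "cv-data"))
    cohort = generate_cohort(cfg)
    mc = model_config if model_config is not None else ModelConfig()
    result = cross_validate(cohort, mc, k=k, seed=substream_seed(seed, "cv"))
    result["n_samples"] = cohort.n_samples
    return result
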