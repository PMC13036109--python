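"""Benchmark harness: the graph model, its ablations, and classical baselines.

Each run regenerates a cohort (data seed) and refits every model (model
seed), so the reported mean +/- sd reflects both data and model variability.
Baselines consume the flat z-scored matrix; only the graph variants see the
co-expression graph.  Scaler, graph and partition are refit per run from
that run's training split (anti-leakage).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import autodiff as ad
from ._rng import substream, substream_seed
from .autodiff import Tensor
from .graph import build_graph, louvain_partition
from .model import (ModelConfig, evaluate_metrics, predict_proba, train_model)
from .simulate import (SimulationConfig, TABLE_SPLIT_COUNTS, generate_cohort,
                       stratified_split, zscore_normalize)

__all__ = [
    "BenchmarkConfig",
    "FullyConnectedNet",
    "run_benchmark",
    "summarize",
    "write_report",
    "reduced_profile",
    "DEFAULT_ROSTER",
]

logger = logging.getLogger(__name__)

DEFAULT_ROSTER = (
    "logistic_regression",
    "random_forest",
    "gradient_boosting",
    "xgboost",
    "svm",
    "knn",
    "naive_bayes",
    "decision_tree",
    "adaboost",
    "extra_trees",
    "bagging",
    "lda",
    "fcnn",
    "full",
    "vae_only",
    "gat_only",
)

METRIC_COLUMNS = ("auc", "accuracy", "precision", "recall", "f1")


def reduced_profile(seed: int = 0, deg_allocation: str = "graded") -> SimulationConfig:
    """Desk-scale study profile: 600 genes in 20 modules of 30, 12 DEGs.

    Preserves the full design's DEG fraction (2%), effect-size distribution,
    correlation structure and sample counts while shrinking the gene
    universe so the graph variants train in seconds on one CPU.
    """
    return SimulationConfig(
        n_genes=600, n_modules=20, n_deg_up=6, n_deg_down=6,
        deg_allocation=deg_allocation, seed=seed,
    )


@dataclass(frozen=True)
class BenchmarkConfig:
    roster: tuple[str, ...] = DEFAULT_ROSTER
    n_runs: int = 5
    base_seed: int = 0
    scale: str = "reduced"  # {"full", "reduced"}
    graph_fraction: float = 0.01
    gamma: float = 4.0
    model_config: ModelConfig = field(default_factory=ModelConfig)
    sim_config: Optional[SimulationConfig] = None
    target_counts: Optional[dict[int, int]] = None

    def __post_init__(self) -> None:
        if not self.roster:
            raise ValueError("roster must be nonempty")
        if self.n_runs < 2:
            raise ValueError("need n_runs >= 2 for a standard deviation")

    def simulation_config(self, seed: int) -> SimulationConfig:
        if self.sim_config is not None:
            return replace(self.sim_config, seed=seed)
        if self.scale == "full":
            return SimulationConfig(seed=seed)
        return reduced_profile(seed=seed)


class FullyConnectedNet:
    """Flat feed-forward baseline: input -> 256 -> 64 -> logit.

    Dropout 0.3 after each hidden layer, same optimiser and early-stopping
    regime as the graph model — the architecture-free control.
    """

    def __init__(self, hidden: tuple[int, int] = (256, 64), dropout: float = 0.3,
                 lr: float = 1e-3, l2: float = 1e-4, max_epochs: int = 100,
                 batch_size: int = 32, patience: int = 10, seed: int = 0):
        self.hidden = hidden
        self.dropout = dropout
        self.lr = lr
        self.l2 = l2
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.patience = patience
        self.seed = seed
        self.params: dict[str, Tensor] = {}

    def _init(self, d: int, rng: np.random.Generator) -> None:
        def glorot(m, n):
            lim = np.sqrt(6.0 / (m + n))
            return Tensor(rng.uniform(-lim, lim, size=(m, n)).astype(np.float32),
                          requires_grad=True)

        h1, h2 = self.hidden
        self.params = {
            "w1": glorot(d, h1), "b1_bias": Tensor(np.zeros(h1, np.float32), requires_grad=True),
            "w2": glorot(h1, h2), "b2_bias": Tensor(np.zeros(h2, np.float32), requires_grad=True),
            "w3": glorot(h2, 1), "b3_bias": Tensor(np.zeros(1, np.float32), requires_grad=True),
        }

    def _logit(self, x: Tensor, train: bool, rng) -> Tensor:
        h = (x @ self.params["w1"] + self.params["b1_bias"]).relu().dropout(
            self.dropout, rng, train)
        h = (h @ self.params["w2"] + self.params["b2_bias"]).relu().dropout(
            self.dropout, rng, train)
        return (h @ self.params["w3"] + self.params["b3_bias"]).reshape(x.data.shape[0])

    def fit(self, x: np.ndarray, y: np.ndarray) -> "FullyConnectedNet":
        from sklearn.metrics import roc_auc_score

        x = np.asarray(x, dtype=np.float32)
        y = np.asarray(y, dtype=np.float32)
        rng_init = substream(self.seed, "fcnn-init")
        rng_batch = substream(self.seed, "fcnn-batches")
        rng_drop = substream(self.seed, "fcnn-dropout")
        rng_val = substream(self.seed, "fcnn-val")
        self._init(x.shape[1], rng_init)
        opt = ad.Adam(self.params, lr=self.lr, weight_decay=self.l2)

        val_parts, fit_parts = [], []
        for label in np.unique(y):
            members = np.flatnonzero(y == label)
            k = max(1, int(round(0.15 * members.size)))
            perm = rng_val.permutation(members)
            val_parts.append(perm[:k])
            fit_parts.append(perm[k:])
        val_idx = np.concatenate(val_parts)
        fit_idx = np.concatenate(fit_parts)

        best_auc, best_state, wait = -np.inf, None, 0
        for _epoch in range(self.max_epochs):
            order = rng_batch.permutation(fit_idx)
            for start in range(0, order.size, self.batch_size):
                idx = order[start : start + self.batch_size]
                opt.zero_grad()
                logit = self._logit(Tensor(x[idx]), True, rng_drop)
                loss = (logit.softplus() - logit * Tensor(y[idx])).mean()
                loss.backward(np.ones(()))
                opt.step()
            val_p = self.predict_proba_matrix(x[val_idx])
            try:
                auc = roc_auc_score(y[val_idx], val_p)
            except ValueError:
                auc = np.nan
            if np.isfinite(auc) and auc > best_auc + 1e-4:
                best_auc = auc
                best_state = {k: v.data.copy() for k, v in self.params.items()}
                wait = 0
            else:
                wait += 1
                if wait >= self.patience:
                    break
        if best_state is not None:
            for k, v in self.params.items():
                v.data = best_state[k]
        return self

    def predict_proba_matrix(self, x: np.ndarray) -> np.ndarray:
        logit = self._logit(Tensor(np.asarray(x, dtype=np.float32)), False, None)
        return 1.0 / (1.0 + np.exp(-logit.data.astype(np.float64)))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:  # sklearn-style (n, 2)
        p = self.predict_proba_matrix(x)
        return np.column_stack([1.0 - p, p])


def _sklearn_baseline(name: str, seed: int):
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.ensemble import (AdaBoostClassifier, BaggingClassifier,
                                  ExtraTreesClassifier, GradientBoostingClassifier,
                                  RandomForestClassifier)
    from sklearn.linear_model import LogisticRegression
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier
    from xgboost import XGBClassifier

    factories = {
        "logistic_regression": lambda: LogisticRegression(max_iter=2000, random_state=seed),
        "random_forest": lambda: RandomForestClassifier(random_state=seed, n_jobs=1),
        "gradient_boosting": lambda: GradientBoostingClassifier(random_state=seed),
        "xgboost": lambda: XGBClassifier(random_state=seed, n_jobs=1),
        "svm": lambda: SVC(probability=True, random_state=seed),
        "knn": lambda: KNeighborsClassifier(),
        "naive_bayes": lambda: GaussianNB(),
        "decision_tree": lambda: DecisionTreeClassifier(random_state=seed),
        "adaboost": lambda: AdaBoostClassifier(random_state=seed),
        "extra_trees": lambda: ExtraTreesClassifier(random_state=seed, n_jobs=1),
        "bagging": lambda: BaggingClassifier(random_state=seed, n_jobs=1),
        "lda": lambda: LinearDiscriminantAnalysis(),
    }
    return factories[name]()


GRAPH_VARIANTS = ("full", "vae_only", "gat_only")


def run_benchmark(config: BenchmarkConfig) -> pd.DataFrame:
    """One row per (model, run) with the standard metric panel.

    Failures are recorded per cell (metrics NaN, error message kept) and the
    run continues.
    """
    rows = []
    for run in range(config.n_runs):
        data_seed = substream_seed(config.base_seed, f"bench-data-{run}")
        model_seed = substream_seed(config.base_seed, f"bench-model-{run}")
        sim = config.simulation_config(data_seed)
        cohort = generate_cohort(sim)
        target = config.target_counts
        if target is None and sim.n_ra == 240 and sim.n_control == 120:
            target = TABLE_SPLIT_COUNTS["train"]
        split = stratified_split(cohort, target_counts=target,
                                 seed=substream_seed(data_seed, "bench-split"))
        train_z = zscore_normalize(split.train)
        test_z = zscore_normalize(split.test, reference=split.train)
        x_tr, y_tr = train_z.expression, train_z.labels
        x_te, y_te = test_z.expression, test_z.labels

        graph = partition = None
        if any(m in GRAPH_VARIANTS for m in config.roster):
            graph = build_graph(train_z, fraction=config.graph_fraction, gamma=config.gamma)
            partition = louvain_partition(graph, seed=substream_seed(model_seed, "louvain"))

        for name in config.roster:
            row = {"model": name, "run": run, "data_seed": data_seed,
                   "model_seed": model_seed}
            try:
                if name in GRAPH_VARIANTS:
                    mc = replace(config.model_config, variant=name, seed=model_seed)
                    g = None if name == "vae_only" else graph
                    trained = train_model(train_z, g, partition, mc)
                    p = predict_proba(trained, test_z)
                elif name == "fcnn":
                    net = FullyConnectedNet(seed=model_seed).fit(x_tr, y_tr)
                    p = net.predict_proba_matrix(x_te)
                else:
                    est = _sklearn_baseline(name, model_seed).fit(x_tr, y_tr)
                    p = est.predict_proba(x_te)[:, 1]
                row.update(evaluate_metrics(p, y_te))
            except Exception as exc:  # record and continue
                logger.warning("model %s failed on run %d: %s", name, run, exc)
                row.update({k: np.nan for k in METRIC_COLUMNS})
                row["error"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample-sd per model over runs."""
    agg = results.groupby("model")[list(METRIC_COLUMNS)].agg(["mean", "std"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    return agg.reset_index()


def write_report(results: pd.DataFrame, path: str) -> pd.DataFrame:
    """Write raw rows plus a 'mean +/- sd' table (3 decimals) next to them."""
    results.to_csv(path, index=False)
    summary = summarize(results)
    pretty = pd.DataFrame({"model": summary["model"]})
    for m in METRIC_COLUMNS:
        pretty[m] = [
            f"{mu:.3f} ± {sd:.3f}" for mu, sd in zip(summary[f"{m}_mean"],
                                                          summary[f"{m}_std"])
        ]
    summary_path = str(path).replace(".csv", "") + "_summary.csv"
    pretty.to_csv(summary_path, index=False)
    return pretty
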