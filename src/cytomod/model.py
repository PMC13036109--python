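"""The co-expression VAE + graph-attention classifier.

Per sample, the network maps a z-scored expression vector to a disease
probability in five stages:

1. **Gene-wise encoder** — a shared map applied to every gene's
   (expression value, learned gene-identity embedding) pair yields one
   node embedding per gene:  h_i = tanh(x_i * w_x + E_i W_g + b).
2. **Variational head** — mean-pooling the node embeddings gives a sample
   summary from which mu and log sigma^2 of the latent z are read out;
   z = mu + sigma * eps (reparameterisation; z = mu in evaluation).  A
   linear decoder reconstructs the expression vector from z for the
   reconstruction loss.
3. **Graph attention** — multi-head attention message passing over the
   co-expression graph updates node embeddings; the edge weight |r|^gamma
   enters each attention logit as an additive bias kappa * ln(w) with
   learnable kappa >= 0, preserving softmax normalisation while letting
   strong correlations dominate.
4. **Module pooling** — node embeddings are averaged within each detected
   gene module, giving one embedding row per module.
5. **Classification head** — the flattened module embeddings pass through
   a 2-layer MLP (64 hidden units, ReLU, dropout 0.3) to a logit and
   sigmoid probability.

Training minimises  L_total = L_BCE + alpha * L_MSE + beta * L_KL  with
Adam, L2 weight decay, and early stopping on a validation fold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Optional

import numpy as np
from sklearn.metrics import roc_auc_score

from . import autodiff as ad
from ._rng import substream, substream_seed
from .autodiff import SegmentPlan, Tensor, concat, gather, segment_sum
from .graph import CoexpressionGraph, ModulePartition, build_graph, louvain_partition
from .simulate import ExpressionCohort, stratified_split, zscore_normalize

__all__ = [
    "ModelConfig",
    "LatentState",
    "Prediction",
    "LossBreakdown",
    "TrainedModel",
    "GeneModuleNet",
    "encode",
    "kl_term",
    "gat_propagate",
    "module_pool",
    "classify",
    "total_loss",
    "train_model",
    "predict_proba",
    "evaluate_metrics",
    "cross_validate",
    "save_model",
    "load_model",
]

VARIANTS = ("full", "vae_only", "gat_only")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and optimisation settings.

    ``init_scheme='de_screen'`` seeds the per-gene encoder slopes with the
    training split's per-gene Welch t-statistics (a standard differential-
    expression screen), so module-pooled features are label-informative from
    the first epoch; gradient descent then refines all parameters jointly.
    ``'random'`` gives a conventional random initialisation.
    """

    node_dim: int = 32
    latent_dim: int = 64
    gene_embed_dim: int = 4
    gat_heads: int = 4
    gat_layers: int = 1
    mlp_hidden: int = 64
    dropout_rate: float = 0.3
    alpha: float = 0.5
    beta: float = 0.1
    l2_lambda: float = 0.1
    learning_rate: float = 1e-3
    max_epochs: int = 100
    batch_size: int = 32
    early_stop_patience: int = 10
    val_fraction: float = 0.25
    grad_clip: float = 5.0
    init_scheme: str = "de_screen"  # {"de_screen", "random"}
    variant: str = "full"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.init_scheme not in ("de_screen", "random"):
            raise ValueError("init_scheme must be 'de_screen' or 'random'")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        for name in ("node_dim", "latent_dim", "gene_embed_dim", "gat_heads",
                     "mlp_hidden", "max_epochs", "batch_size", "early_stop_patience"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.node_dim % self.gat_heads != 0:
            raise ValueError("node_dim must be divisible by gat_heads")


@dataclass
class LatentState:
    mu: np.ndarray
    sigma: np.ndarray
    z: np.ndarray
    node_embeddings: np.ndarray


@dataclass
class Prediction:
    p: np.ndarray
    logit: np.ndarray


@dataclass
class LossBreakdown:
    total: float
    bce: float
    mse: float
    kl: float


def kl_term(mu: np.ndarray, sigma: np.ndarray) -> float:
    """KL( N(mu, diag sigma^2) || N(0, I) ), averaged over samples.

    Closed form sum_d 0.5 * (mu_d^2 + sigma_d^2 - 1 - ln sigma_d^2).
    """
    mu = np.atleast_2d(np.asarray(mu, dtype=np.float64))
    sigma = np.atleast_2d(np.asarray(sigma, dtype=np.float64))
    if (sigma <= 0).any():
        raise ValueError("sigma must be strictly positive")
    per_sample = 0.5 * (mu**2 + sigma**2 - 1.0 - 2.0 * np.log(sigma)).sum(axis=1)
    return float(per_sample.mean())


class GeneModuleNet:
    """Parameter container + forward pass for all three architecture variants."""

    def __init__(
        self,
        n_genes: int,
        partition: ModulePartition,
        graph: Optional[CoexpressionGraph],
        config: ModelConfig,
        rng: Optional[np.random.Generator] = None,
        gene_scores: Optional[np.ndarray] = None,
    ):
        if partition.n_genes != n_genes:
            raise ValueError("partition does not cover the gene universe")
        if config.variant != "vae_only":
            if graph is None:
                raise ValueError(f"variant {config.variant!r} requires a graph")
            if graph.n_nodes != n_genes:
                raise ValueError("graph node count must equal gene count")
        self.n_genes = n_genes
        self.config = config
        self.partition = partition
        self.graph = graph
        rng = rng if rng is not None else substream(config.seed, "model-init")

        self.module_plan = SegmentPlan(partition.module_of_gene, partition.n_modules)
        counts = self.module_plan.counts()
        if (counts == 0).any():
            raise ValueError("partition contains an empty module")
        self._module_counts = counts.astype(np.float32)[None, :, None]
        self.n_modules = partition.n_modules

        if config.variant != "vae_only":
            src, dst, w = graph.directed_with_self_loops()
            self.src_plan = SegmentPlan(src, n_genes)
            self.dst_plan = SegmentPlan(dst, n_genes)
            self._lnw = np.maximum(np.log(np.maximum(w, 1e-30)), -20.0).astype(np.float32)[
                None, :, None
            ]

        D, L, g, H = config.node_dim, config.latent_dim, config.gene_embed_dim, config.gat_heads
        Dh = D // H
        M = self.n_modules

        def glorot(*shape):
            fan_in, fan_out = shape[0], shape[-1]
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return Tensor(rng.uniform(-lim, lim, size=shape).astype(np.float32),
                          requires_grad=True)

        def zeros(*shape):
            return Tensor(np.zeros(shape, dtype=np.float32), requires_grad=True)

        p: dict[str, Tensor] = {
            "gene_emb": Tensor(rng.normal(0, 0.1, size=(n_genes, g)).astype(np.float32),
                               requires_grad=True),
            "enc_wx": Tensor(rng.normal(0, 0.5, size=(D,)).astype(np.float32),
                             requires_grad=True),
            "enc_ws": glorot(g, D),
            "enc_wg": glorot(g, D),
            "enc_bias": zeros(D),
            "clf_w1": glorot(M * D, config.mlp_hidden),
            "clf_b1_bias": zeros(config.mlp_hidden),
            "clf_w2": glorot(config.mlp_hidden, 1),
            "clf_b2_bias": zeros(1),
        }
        if config.variant != "gat_only":
            p.update({
                "mu_w": glorot(D, L), "mu_bias": zeros(L),
                "lv_w": glorot(D, L), "lv_bias": zeros(L),
                "dec_w": glorot(L, n_genes), "dec_bias": zeros(n_genes),
            })
        if config.variant != "vae_only":
            p["gat_w"] = glorot(D, D)  # H heads of width Dh, fused
            p["gat_asrc"] = Tensor(rng.normal(0, 0.1, size=(H, Dh)).astype(np.float32),
                                   requires_grad=True)
            p["gat_adst"] = Tensor(rng.normal(0, 0.1, size=(H, Dh)).astype(np.float32),
                                   requires_grad=True)
            p["gat_kappa"] = Tensor(np.zeros(1, dtype=np.float32), requires_grad=True)
        self.params = p
        if gene_scores is not None:
            self._apply_gene_score_init(np.asarray(gene_scores, dtype=np.float64))

    def _apply_gene_score_init(self, scores: np.ndarray) -> None:
        """Seed per-gene slopes with a differential-expression score.

        The first gene-embedding coordinate carries the (clipped, scaled)
        score and is routed into every slope dimension; the shared base slope
        and remaining embedding directions start quiet so that module-pooled
        features begin as score-weighted module averages rather than plain
        module means, which are dominated by label-independent factor noise.
        """
        if scores.shape != (self.n_genes,):
            raise ValueError("gene_scores must have one value per gene")
        scaled = np.clip(scores / 3.0, -2.0, 2.0).astype(np.float32)
        rng = substream(self.config.seed, "score-init")
        self.params["enc_wx"].data[:] = rng.normal(
            0.0, 0.05, self.config.node_dim).astype(np.float32)
        self.params["gene_emb"].data[:, 0] = scaled
        self.params["enc_ws"].data[0, :] = 0.5
        self.params["enc_ws"].data[1:, :] *= 0.1
        self.params["enc_wg"].data *= 0.1

    # ------------------------------------------------------------------ #
    def encode_nodes(self, x: Tensor) -> Tensor:
        """(B, N) expression -> (B, N, D) node embeddings.

        Shared map over (expression value, gene-identity embedding) with an
        interaction term: the embedding contributes both an additive offset
        and a per-gene slope, so the encoder can selectively amplify or mute
        individual genes.
        """
        B, N = x.data.shape
        gene_term = self.params["gene_emb"] @ self.params["enc_wg"]  # (N, D)
        slope = self.params["gene_emb"] @ self.params["enc_ws"] + self.params["enc_wx"]
        pre = x.reshape(B, N, 1) * slope + gene_term + self.params["enc_bias"]
        return pre.tanh()

    def variational(self, h: Tensor, sample: bool, rng: Optional[np.random.Generator]):
        hbar = h.mean(axis=1)  # (B, D)
        mu = hbar @ self.params["mu_w"] + self.params["mu_bias"]
        logvar = hbar @ self.params["lv_w"] + self.params["lv_bias"]
        if sample:
            eps = Tensor(rng.standard_normal(mu.data.shape).astype(np.float32))
            z = mu + (logvar * 0.5).exp() * eps
        else:
            z = mu
        xhat = z @ self.params["dec_w"] + self.params["dec_bias"]
        return mu, logvar, z, xhat

    def gat(self, h: Tensor) -> Tensor:
        """Multi-head attention message passing over the co-expression graph.

        All heads run fused as a (B, E, H, Dh) computation; attention is
        softmax-normalised over each node's in-neighbourhood (self-loop
        included), with kappa * ln(w_ij) as an additive logit bias.
        """
        B, N = h.data.shape[0], h.data.shape[1]
        H = self.config.gat_heads
        Dh = self.config.node_dim // H
        kappa = self.params["gat_kappa"].softplus()
        wh = (h @ self.params["gat_w"]).reshape(B, N, H, Dh)
        s_src = (wh * self.params["gat_asrc"]).sum(axis=3)  # (B, N, H)
        s_dst = (wh * self.params["gat_adst"]).sum(axis=3)
        logits = (gather(s_src, self.src_plan) + gather(s_dst, self.dst_plan)).leaky_relu(
            0.2
        ) + kappa * Tensor(self._lnw)  # (B, E, H)
        shift = self.dst_plan.segment_reduce(logits.data, np.maximum)  # (B, N, H)
        num = (logits - Tensor(shift[:, self.dst_plan.idx])).exp()
        denom = segment_sum(num, self.dst_plan)  # (B, N, H)
        att = (num / gather(denom, self.dst_plan)).reshape(B, -1, H, 1)
        messages = att * gather(wh, self.src_plan)  # (B, E, H, Dh)
        out = segment_sum(messages, self.dst_plan)  # (B, N, H, Dh)
        return out.reshape(B, N, H * Dh).elu()

    def pool_modules(self, node_h: Tensor) -> Tensor:
        return segment_sum(node_h, self.module_plan) * Tensor(1.0 / self._module_counts)

    def head(self, pooled: Tensor, train: bool, rng: Optional[np.random.Generator]) -> Tensor:
        B = pooled.data.shape[0]
        flat = pooled.reshape(B, self.n_modules * self.config.node_dim)
        h1 = (flat @ self.params["clf_w1"] + self.params["clf_b1_bias"]).relu()
        h1 = h1.dropout(self.config.dropout_rate, rng, train)
        return (h1 @ self.params["clf_w2"] + self.params["clf_b2_bias"]).reshape(B)

    def forward(
        self,
        x: np.ndarray,
        train: bool = False,
        sample: bool = False,
        rng: Optional[np.random.Generator] = None,
    ) -> dict:
        xt = Tensor(np.asarray(x, dtype=np.float32))
        node_h = self.encode_nodes(xt)
        out: dict = {"x": xt, "node_h": node_h}
        if self.config.variant != "gat_only":
            mu, logvar, z, xhat = self.variational(node_h, sample, rng)
            out.update(mu=mu, logvar=logvar, z=z, xhat=xhat)
        propagated = node_h if self.config.variant == "vae_only" else self.gat(node_h)
        out["gat_out"] = propagated
        pooled = self.pool_modules(propagated)
        out["module_emb"] = pooled
        logit = self.head(pooled, train, rng)
        out["logit"] = logit
        out["p"] = logit.sigmoid()
        return out

    def parameter_state(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_parameter_state(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            v.data = state[k].astype(v.data.dtype)


# ---------------------------------------------------------------------- #
# spec-level operation surface (thin functional wrappers, evaluation mode)


def encode(net: GeneModuleNet, expression: np.ndarray,
           sample: bool = False, rng: Optional[np.random.Generator] = None) -> LatentState:
    """Gene-wise encoding + variational head for one or more samples."""
    x = np.atleast_2d(np.asarray(expression, dtype=np.float32))
    if x.shape[1] != net.n_genes:
        raise ValueError("expression length must equal the gene count")
    if net.config.variant == "gat_only":
        raise ValueError("gat_only variant has no variational head")
    h = net.encode_nodes(Tensor(x))
    mu, logvar, z, _ = net.variational(h, sample, rng)
    sigma = np.exp(0.5 * logvar.data.astype(np.float64))
    return LatentState(mu=mu.data.copy(), sigma=sigma, z=z.data.copy(),
                       node_embeddings=h.data.copy())


def gat_propagate(net: GeneModuleNet, node_embeddings: np.ndarray) -> np.ndarray:
    """Run the attention layer on given node embeddings (B, N, D)."""
    emb = np.asarray(node_embeddings, dtype=np.float32)
    if emb.ndim == 2:
        emb = emb[None]
    if emb.shape[1] != net.n_genes:
        raise ValueError("node count mismatch with the graph")
    return net.gat(Tensor(emb)).data.copy()


def module_pool(node_embeddings: np.ndarray, partition: ModulePartition) -> np.ndarray:
    """Unweighted per-module mean of node embeddings (plain numpy)."""
    emb = np.asarray(node_embeddings)
    squeeze = emb.ndim == 2
    if squeeze:
        emb = emb[None]
    if emb.shape[1] != partition.n_genes:
        raise ValueError("partition does not cover the embedding rows")
    sizes = partition.module_sizes
    if (sizes == 0).any():
        raise ValueError("partition contains an empty module")
    plan = SegmentPlan(partition.module_of_gene, partition.n_modules)
    pooled = plan.segment_reduce(emb.astype(np.float64)) / sizes[None, :, None]
    return pooled[0] if squeeze else pooled


def classify(net: GeneModuleNet, module_embeddings: np.ndarray) -> Prediction:
    """Classification head only: module embeddings (B, M, D) -> probability."""
    emb = np.asarray(module_embeddings, dtype=np.float32)
    if emb.ndim == 2:
        emb = emb[None]
    if emb.shape[1] != net.n_modules:
        raise ValueError(
            f"module count {emb.shape[1]} does not match trained head ({net.n_modules})"
        )
    logit = net.head(Tensor(emb), train=False, rng=None)
    p = 1.0 / (1.0 + np.exp(-logit.data.astype(np.float64)))
    return Prediction(p=p, logit=logit.data.astype(np.float64))


def total_loss(net: GeneModuleNet, x: np.ndarray, y: np.ndarray,
               alpha: Optional[float] = None, beta: Optional[float] = None,
               train: bool = False, sample: bool = False,
               rng: Optional[np.random.Generator] = None) -> tuple[Tensor, LossBreakdown]:
    """Composite loss L_BCE + alpha * L_MSE + beta * L_KL on one batch.

    Returns the differentiable total plus a float breakdown.  For the
    gat_only variant the variational terms are identically zero.
    """
    y = np.asarray(y)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    alpha = net.config.alpha if alpha is None else alpha
    beta = net.config.beta if beta is None else beta
    out = net.forward(x, train=train, sample=sample, rng=rng)
    logit = out["logit"]
    yt = Tensor(y.astype(np.float32))
    bce = (logit.softplus() - logit * yt).mean()
    if net.config.variant == "gat_only":
        total = bce
        return total, LossBreakdown(float(total.data), float(bce.data), 0.0, 0.0)
    mu, logvar, xhat = out["mu"], out["logvar"], out["xhat"]
    mse = ((xhat - out["x"]) ** 2).mean()
    kl = ((mu**2 + logvar.exp() - logvar - 1.0) * 0.5).sum(axis=1).mean()
    total = bce + alpha * mse + beta * kl
    return total, LossBreakdown(float(total.data), float(bce.data),
                                float(mse.data), float(kl.data))


# ---------------------------------------------------------------------- #


@dataclass
class TrainedModel:
    net: GeneModuleNet
    config: ModelConfig
    partition: ModulePartition
    gene_ids: np.ndarray
    history: list = field(default_factory=list)
    module_mean: Optional[np.ndarray] = None  # (M, D) over training samples
    module_sigma: Optional[np.ndarray] = None  # (M, D) per-dimension sd
    scaler_mean: Optional[np.ndarray] = None
    scaler_sd: Optional[np.ndarray] = None

    def module_embeddings(self, cohort: ExpressionCohort, batch: int = 256) -> np.ndarray:
        """(n_samples, M, D) module embeddings in evaluation mode."""
        self._check_genes(cohort)
        outs = []
        for start in range(0, cohort.n_samples, batch):
            out = self.net.forward(cohort.expression[start : start + batch])
            outs.append(out["module_emb"].data.astype(np.float64))
        return np.concatenate(outs, axis=0)

    def _check_genes(self, cohort: ExpressionCohort) -> None:
        if cohort.n_genes != self.net.n_genes:
            raise ValueError("cohort gene universe does not match the trained model")


def welch_t_scores(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-gene Welch t-statistic between the two label groups."""
    a, b = x[y == 1], x[y == 0]
    se = np.sqrt(a.var(axis=0) / a.shape[0] + b.var(axis=0) / b.shape[0] + 1e-12)
    return (a.mean(axis=0) - b.mean(axis=0)) / se


def _clip_gradients(params: dict[str, Tensor], max_norm: float) -> None:
    total = 0.0
    for p in params.values():
        if p.grad is not None:
            total += float((p.grad.astype(np.float64) ** 2).sum())
    norm = np.sqrt(total)
    if norm > max_norm:
        scale = max_norm / (norm + 1e-12)
        for p in params.values():
            if p.grad is not None:
                p.grad = p.grad * scale


def train_model(
    train: ExpressionCohort,
    graph: Optional[CoexpressionGraph],
    partition: ModulePartition,
    config: ModelConfig,
    verbose: bool = False,
) -> TrainedModel:
    """Mini-batch training with early stopping on a validation-fold AUC.

    ``train`` must already be z-scored; the graph must come from the same
    training split (anti-leakage).  15% of the training samples (stratified)
    are held out for early stopping and restored to the best epoch.
    """
    x_all = train.expression.astype(np.float32)
    y_all = train.labels.astype(np.float32)

    rng_val = substream(config.seed, "val-split")
    val_idx_parts = []
    train_idx_parts = []
    for label in np.unique(train.labels):
        members = np.flatnonzero(train.labels == label)
        k = max(1, int(round(config.val_fraction * members.size)))
        perm = rng_val.permutation(members)
        val_idx_parts.append(perm[:k])
        train_idx_parts.append(perm[k:])
    val_idx = np.sort(np.concatenate(val_idx_parts))
    fit_idx = np.sort(np.concatenate(train_idx_parts))

    gene_scores = None
    if config.init_scheme == "de_screen":
        gene_scores = welch_t_scores(train.expression[fit_idx], train.labels[fit_idx])
    net = GeneModuleNet(train.n_genes, partition, graph, config,
                        gene_scores=gene_scores)

    opt = ad.Adam(net.params, lr=config.learning_rate, weight_decay=config.l2_lambda)
    rng_batch = substream(config.seed, "batches")
    rng_drop = substream(config.seed, "dropout")
    rng_eps = substream(config.seed, "vae-noise")

    best_auc, best_state, patience = -np.inf, None, 0
    history = []
    sample_latent = config.variant != "gat_only"
    for epoch in range(config.max_epochs):
        order = rng_batch.permutation(fit_idx)
        losses = []
        for start in range(0, order.size, config.batch_size):
            idx = order[start : start + config.batch_size]
            opt.zero_grad()
            total, parts = total_loss(
                net, x_all[idx], y_all[idx], train=True, sample=sample_latent,
                rng=_MergedRng(rng_drop, rng_eps),
            )
            if not np.isfinite(parts.total):
                raise RuntimeError(f"training diverged (non-finite loss) at epoch {epoch}")
            total.backward(np.ones(()))
            _clip_gradients(net.params, config.grad_clip)
            opt.step()
            losses.append(parts)
        val_p = _predict_array(net, x_all[val_idx])
        try:
            val_auc = roc_auc_score(train.labels[val_idx], val_p)
        except ValueError:
            val_auc = np.nan
        record = {
            "epoch": epoch,
            "loss": float(np.mean([l.total for l in losses])),
            "bce": float(np.mean([l.bce for l in losses])),
            "mse": float(np.mean([l.mse for l in losses])),
            "kl": float(np.mean([l.kl for l in losses])),
            "val_auc": float(val_auc),
        }
        history.append(record)
        if verbose:
            print(f"epoch {epoch}: loss {record['loss']:.4f} val_auc {val_auc:.4f}")
        if np.isfinite(val_auc) and val_auc > best_auc + 1e-4:
            best_auc, best_state, patience = val_auc, net.parameter_state(), 0
        else:
            patience += 1
            if patience >= config.early_stop_patience:
                break
    if best_state is not None:
        net.load_parameter_state(best_state)

    trained = TrainedModel(net=net, config=config, partition=partition,
                           gene_ids=np.asarray(train.gene_ids), history=history)
    emb = trained.module_embeddings(train)
    trained.module_mean = emb.mean(axis=0)
    trained.module_sigma = emb.std(axis=0)
    return trained


class _MergedRng:
    """Routes dropout draws and latent-noise draws to their own substreams."""

    def __init__(self, rng_dropout: np.random.Generator, rng_eps: np.random.Generator):
        self._drop = rng_dropout
        self._eps = rng_eps

    def random(self, shape):  # dropout masks
        return self._drop.random(shape)

    def standard_normal(self, shape):  # reparameterisation noise
        return self._eps.standard_normal(shape)


def _predict_array(net: GeneModuleNet, x: np.ndarray, batch: int = 512) -> np.ndarray:
    ps = []
    for start in range(0, x.shape[0], batch):
        out = net.forward(x[start : start + batch])
        ps.append(out["p"].data.astype(np.float64))
    return np.concatenate(ps)


def predict_proba(trained: TrainedModel, cohort: ExpressionCohort) -> np.ndarray:
    """Per-sample disease probability, evaluation mode (z = mu, no dropout)."""
    trained._check_genes(cohort)
    return _predict_array(trained.net, cohort.expression.astype(np.float32))


def evaluate_metrics(p: np.ndarray, labels: np.ndarray, threshold: float = 0.5) -> dict:
    """AUC (rank-based, ties half-credited) plus threshold-0.5 class metrics."""
    p = np.asarray(p, dtype=np.float64)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("AUC undefined: labels contain a single class")
    pred = (p > threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {
        "auc": float(roc_auc_score(labels, p)),
        "accuracy": (tp + tn) / labels.size,
        "precision": precision,
        "recall": recall,
        "f1": f1,
    }


def cross_validate(
    cohort: ExpressionCohort,
    config: ModelConfig,
    k: int = 5,
    fraction: float = 0.01,
    gamma: float = 4.0,
    seed: int = 0,
) -> dict:
    """Stratified k-fold CV; scaler, graph and partition refit inside each fold."""
    from sklearn.model_selection import StratifiedKFold

    if k < 2:
        raise ValueError("need at least 2 folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True,
                          random_state=substream_seed(seed, "cv-folds"))
    fold_metrics = []
    pooled_p, pooled_y = [], []
    for fold, (tr, te) in enumerate(skf.split(cohort.expression, cohort.labels)):
        if np.unique(cohort.labels[tr]).size < 2:
            raise ValueError(f"fold {fold} training split contains a single class")
        train_c = cohort.subset(tr, name=f"cv{fold}-train")
        test_c = cohort.subset(te, name=f"cv{fold}-test")
        train_z = zscore_normalize(train_c)
        test_z = zscore_normalize(test_c, reference=train_c)
        g = build_graph(train_z, fraction=fraction, gamma=gamma)
        part = louvain_partition(g, seed=substream_seed(seed, f"cv-louvain-{fold}"))
        fold_config = replace(config, seed=substream_seed(seed, f"cv-model-{fold}"))
        trained = train_model(train_z, g, part, fold_config)
        p = predict_proba(trained, test_z)
        pooled_p.append(p)
        pooled_y.append(test_c.labels)
        if np.unique(test_c.labels).size >= 2:
            fold_metrics.append(evaluate_metrics(p, test_c.labels))
    result: dict = {"folds": fold_metrics}
    # leave-one-out-style folds have single-class test sets; AUC is then
    # defined only on the pooled held-out predictions
    result["pooled"] = evaluate_metrics(np.concatenate(pooled_p),
                                        np.concatenate(pooled_y))
    if fold_metrics:
        keys = fold_metrics[0].keys()
        summary = {f"mean_{k_}": float(np.mean([m[k_] for m in fold_metrics]))
                   for k_ in keys}
        summary.update({f"sd_{k_}": float(np.std([m[k_] for m in fold_metrics],
                                                 ddof=1)) for k_ in keys})
    else:
        summary = {f"mean_{k_}": v for k_, v in result["pooled"].items()}
    result["summary"] = summary
    return result


# ---------------------------------------------------------------------- #
# checkpointing: one npz archive + a plain-text JSON sidecar with hashes


def save_model(trained: TrainedModel, path: str) -> None:
    import hashlib

    arrays = {f"param:{k}": v.data for k, v in trained.net.params.items()}
    arrays["partition"] = trained.partition.module_of_gene
    arrays["gene_ids"] = trained.gene_ids.astype("U")
    arrays["module_mean"] = trained.module_mean
    arrays["module_sigma"] = trained.module_sigma
    if trained.scaler_mean is not None:
        arrays["scaler_mean"] = trained.scaler_mean
        arrays["scaler_sd"] = trained.scaler_sd
    g = trained.net.graph
    if g is not None:
        arrays.update(graph_edge_a=g.edge_a, graph_edge_b=g.edge_b, graph_r=g.r,
                      graph_weight=g.weight)
    np.savez_compressed(path, **arrays)
    gene_hash = hashlib.sha256("".join(map(str, trained.gene_ids)).encode()).hexdigest()[:16]
    part_hash = hashlib.sha256(trained.partition.module_of_gene.tobytes()).hexdigest()[:16]
    sidecar = {
        "config": asdict(trained.config),
        "gene_hash": gene_hash,
        "partition_hash": part_hash,
        "graph": None if g is None else {
            "gamma": g.gamma, "threshold_fraction": g.threshold_fraction,
            "n_nodes": g.n_nodes,
        },
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_model(path: str) -> TrainedModel:
    import hashlib

    with open(str(path) + ".json") as fh:
        sidecar = json.load(fh)
    data = np.load(path, allow_pickle=False)
    config = ModelConfig(**sidecar["config"])
    partition = ModulePartition(data["partition"])
    gene_ids = data["gene_ids"]
    gene_hash = hashlib.sha256("".join(map(str, gene_ids)).encode()).hexdigest()[:16]
    if gene_hash != sidecar["gene_hash"]:
        raise ValueError("gene universe hash mismatch in checkpoint")
    part_hash = hashlib.sha256(partition.module_of_gene.tobytes()).hexdigest()[:16]
    if part_hash != sidecar["partition_hash"]:
        raise ValueError("partition hash mismatch in checkpoint")
    graph = None
    if sidecar["graph"] is not None:
        graph = CoexpressionGraph(
            n_nodes=sidecar["graph"]["n_nodes"],
            edge_a=data["graph_edge_a"], edge_b=data["graph_edge_b"],
            r=data["graph_r"], weight=data["graph_weight"],
            gamma=sidecar["graph"]["gamma"],
            threshold_fraction=sidecar["graph"]["threshold_fraction"],
        )
    net = GeneModuleNet(len(gene_ids), partition, graph, config)
    net.load_parameter_state({k[len("param:"):]: data[k] for k in data.files
                              if k.startswith("param:")})
    trained = TrainedModel(net=net, config=config, partition=partition, gene_ids=gene_ids,
                           module_mean=data["module_mean"], module_sigma=data["module_sigma"])
    if "scaler_mean" in data.files:
        trained.scaler_mean = data["scaler_mean"]
        trained.scaler_sd = data["scaler_sd"]
    return trained
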