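"""Synthetic modular gene-expression cohorts with planted differential expression.

The generator emulates a case/control bulk-transcriptomics study: every gene
has unit-variance Gaussian expression; a chosen set of differentially
expressed genes (DEGs) receives a fixed per-gene mean shift in the disease
group; genes are organised into modules whose members share a latent factor,
inducing a target within-module pairwise Pearson correlation (default 0.3)
while cross-module correlation stays at zero.

Within a module the construction is

    x_ij = lambda_i * f_mj + sqrt(1 - lambda_i^2) * e_ij

with a per-sample module factor f_mj ~ N(0,1), gene loading
lambda_i = sqrt(rho) + eta_i, eta_i ~ N(0, (corr_noise_sd/2)^2) clamped to
(0, 1), and idiosyncratic noise e_ij ~ N(0,1).  Marginals stay N(0,1) and
pairwise correlations are lambda_i * lambda_j, centred on rho with spread
governed by ``corr_noise_sd``.  A pairwise-exact correlation matrix at this
scale is not positive definite in general; the single-factor model is the
standard well-posed surrogate.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from ._rng import substream

__all__ = [
    "SimulationConfig",
    "ExpressionCohort",
    "SplitResult",
    "ConfigurationError",
    "generate_cohort",
    "generate_holdout",
    "zscore_normalize",
    "stratified_split",
    "TABLE_SPLIT_COUNTS",
    "RA",
    "CONTROL",
]

logger = logging.getLogger(__name__)

RA = 1
CONTROL = 0
LABEL_NAMES = {RA: "RA", CONTROL: "control"}

#: Printed train/test class counts of the reference study design (252/108 split
#: with 176/76 RA/control in train, 64/44 in test).  Note these are *not* the
#: counts a 70% stratified split of 240/120 would give (168/84); the printed
#: counts are reproduced verbatim via ``target_counts``.
TABLE_SPLIT_COUNTS = {"train": {RA: 176, CONTROL: 76}, "test": {RA: 64, CONTROL: 44}}

#: Designated cytokine-responsive modules under graded DEG allocation, as
#: fractions of all DEGs concentrated into the first three modules.
DEFAULT_GRADED_WEIGHTS = {0: 0.40, 1: 0.25, 2: 0.15}
DESIGNATED_MODULE_NAMES = {0: "IL6-like", 1: "TNFA-like", 2: "IL1B-like"}


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterisation of a synthetic cohort.

    Defaults reproduce the reference study design: 15,000 genes in 100
    modules of 150, 300 DEGs (150 up / 150 down, |shift| ~ U(0.5, 1.5)),
    240 disease and 120 control samples, within-module correlation 0.3.
    """

    n_genes: int = 15_000
    n_deg_up: int = 150
    n_deg_down: int = 150
    n_modules: int = 100
    n_ra: int = 240
    n_control: int = 120
    within_module_corr: float = 0.3
    corr_noise_sd: float = 0.1
    mu_up_range: tuple[float, float] = (0.5, 1.5)
    mu_down_range: tuple[float, float] = (-1.5, -0.5)
    deg_allocation: str = "graded"  # {"uniform", "graded"}
    graded_module_weights: Optional[dict[int, float]] = None
    holdout_corr_shift: tuple[float, float] | float = (-0.05, 0.05)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_modules, self.n_ra, self.n_control) <= 0:
            raise ConfigurationError("counts must be positive")
        if self.n_deg_up < 0 or self.n_deg_down < 0:
            raise ConfigurationError("DEG counts must be nonnegative")
        if self.n_deg_up + self.n_deg_down > self.n_genes:
            raise ConfigurationError("more DEGs requested than genes")
        if not 0.0 < self.within_module_corr < 1.0:
            raise ConfigurationError("within_module_corr must lie in (0, 1)")
        if self.corr_noise_sd < 0:
            raise ConfigurationError("corr_noise_sd must be nonnegative")
        if not (self.mu_up_range[0] > 0 and self.mu_up_range[1] >= self.mu_up_range[0]):
            raise ConfigurationError("mu_up_range must be strictly positive")
        if not (self.mu_down_range[1] < 0 and self.mu_down_range[0] <= self.mu_down_range[1]):
            raise ConfigurationError("mu_down_range must be strictly negative")
        if self.n_genes % self.n_modules != 0:
            raise ConfigurationError(
                f"{self.n_modules} equal modules cannot partition {self.n_genes} genes"
            )
        if self.deg_allocation not in ("uniform", "graded"):
            raise ConfigurationError(f"unknown deg_allocation {self.deg_allocation!r}")
        w = self.graded_weights()
        if self.deg_allocation == "graded":
            if any(m < 0 or m >= self.n_modules for m in w):
                raise ConfigurationError("graded weight module index out of range")
            total = sum(w.values())
            if any(v < 0 for v in w.values()) or total > 1.0 + 1e-9:
                raise ConfigurationError("graded_module_weights must be in [0, 1] and sum to <= 1")

    def graded_weights(self) -> dict[int, float]:
        if self.graded_module_weights is not None:
            return dict(self.graded_module_weights)
        # default designated modules, restricted to the modules that exist
        return {m: f for m, f in DEFAULT_GRADED_WEIGHTS.items() if m < self.n_modules}

    @property
    def module_size(self) -> int:
        return self.n_genes // self.n_modules

    @property
    def n_deg(self) -> int:
        return self.n_deg_up + self.n_deg_down

    @property
    def n_samples(self) -> int:
        return self.n_ra + self.n_control

    def config_hash(self) -> str:
        payload = {k: v for k, v in self.__dict__.items()}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ExpressionCohort:
    """A samples-by-genes expression matrix with ground-truth annotations."""

    expression: np.ndarray  # (n_samples, n_genes) float64
    labels: np.ndarray  # (n_samples,) int, 1 = disease (RA), 0 = control
    gene_ids: np.ndarray  # (n_genes,) str
    true_module_of_gene: np.ndarray  # (n_genes,) int
    deg_effect: np.ndarray  # (n_genes,) float, 0 for background genes
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.expression.ndim != 2:
            raise ValueError("expression must be 2-D (samples x genes)")
        if self.expression.shape[0] != self.labels.shape[0]:
            raise ValueError("labels length must match sample count")
        if self.expression.shape[1] != len(self.gene_ids):
            raise ValueError("gene_ids length must match gene count")
        if np.isnan(self.expression).any():
            raise ValueError("expression contains missing values")

    @property
    def n_samples(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]

    @property
    def sample_ids(self) -> np.ndarray:
        ids = self.provenance.get("sample_ids")
        if ids is not None:
            return np.asarray(ids)
        return np.array([f"S{i:05d}" for i in range(self.n_samples)])

    def class_counts(self) -> dict[int, int]:
        return {int(k): int(v) for k, v in zip(*np.unique(self.labels, return_counts=True))}

    def subset(self, index: np.ndarray, name: str | None = None) -> "ExpressionCohort":
        index = np.asarray(index)
        prov = dict(self.provenance)
        prov["sample_ids"] = self.sample_ids[index]
        if name:
            prov["cohort_name"] = name
        return ExpressionCohort(
            expression=self.expression[index],
            labels=self.labels[index],
            gene_ids=self.gene_ids,
            true_module_of_gene=self.true_module_of_gene,
            deg_effect=self.deg_effect,
            provenance=prov,
        )


@dataclass
class SplitResult:
    train: ExpressionCohort
    test: ExpressionCohort
    holdout: Optional[ExpressionCohort] = None

    @property
    def class_counts(self) -> dict[str, dict[int, int]]:
        out = {"train": self.train.class_counts(), "test": self.test.class_counts()}
        if self.holdout is not None:
            out["holdout"] = self.holdout.class_counts()
        return out


def _deg_layout(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Choose DEG gene indices and their mean shifts.

    Drawn from a dedicated substream of the master seed so that a holdout
    cohort generated from the same config plants *identical* effects.
    """
    rng = substream(config.seed, "degs")
    n_deg = config.n_deg
    module_of_gene = np.repeat(np.arange(config.n_modules), config.module_size)
    chosen: list[int] = []
    if config.deg_allocation == "graded" and n_deg > 0:
        for m, frac in sorted(config.graded_weights().items()):
            k = int(round(frac * n_deg))
            pool = np.setdiff1d(np.flatnonzero(module_of_gene == m), chosen)
            k = min(k, pool.size)
            chosen.extend(rng.choice(pool, size=k, replace=False).tolist())
    remaining = n_deg - len(chosen)
    if remaining > 0:
        pool = np.setdiff1d(np.arange(config.n_genes), chosen)
        chosen.extend(rng.choice(pool, size=remaining, replace=False).tolist())
    deg_genes = np.array(sorted(chosen), dtype=np.int64)

    signs = np.r_[np.ones(config.n_deg_up), -np.ones(config.n_deg_down)]
    rng.shuffle(signs)
    lo_up, hi_up = config.mu_up_range
    lo_dn, hi_dn = config.mu_down_range
    mags_up = rng.uniform(lo_up, hi_up, size=n_deg)
    mags_dn = rng.uniform(lo_dn, hi_dn, size=n_deg)
    effect = np.zeros(config.n_genes)
    effect[deg_genes] = np.where(signs > 0, mags_up, mags_dn)
    return deg_genes, effect


def _loadings(config: SimulationConfig, rho_of_module: np.ndarray) -> np.ndarray:
    """Per-gene factor loadings targeting each module's pairwise correlation."""
    rng = substream(config.seed, "loadings")
    module_of_gene = np.repeat(np.arange(config.n_modules), config.module_size)
    eta = rng.normal(0.0, config.corr_noise_sd / 2.0, size=config.n_genes)
    lam = np.sqrt(rho_of_module[module_of_gene]) + eta
    return np.clip(lam, 1e-3, 1.0 - 1e-3)


def _simulate(
    config: SimulationConfig,
    n_ra: int,
    n_control: int,
    rho_of_module: np.ndarray,
    noise_stream: str,
    cohort_name: str,
) -> ExpressionCohort:
    module_of_gene = np.repeat(np.arange(config.n_modules), config.module_size)
    _, deg_effect = _deg_layout(config)
    lam = _loadings(config, rho_of_module)

    rng = substream(config.seed, noise_stream)
    n = n_ra + n_control
    factors = rng.standard_normal((n, config.n_modules))
    noise = rng.standard_normal((n, config.n_genes))
    expr = factors[:, module_of_gene] * lam + np.sqrt(1.0 - lam**2) * noise
    labels = np.r_[np.full(n_ra, RA), np.full(n_control, CONTROL)]
    expr[labels == RA] += deg_effect  # fixed per-gene shift, zero for background

    gene_ids = np.array([f"G{i:05d}" for i in range(config.n_genes)])
    designated = (
        {m: DESIGNATED_MODULE_NAMES.get(m, f"designated-{m}") for m in config.graded_weights()}
        if config.deg_allocation == "graded"
        else {}
    )
    prov = {
        "cohort_name": cohort_name,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "designated_modules": designated,
    }
    return ExpressionCohort(
        expression=expr,
        labels=labels,
        gene_ids=gene_ids,
        true_module_of_gene=module_of_gene,
        deg_effect=deg_effect,
        provenance=prov,
    )


def generate_cohort(config: SimulationConfig) -> ExpressionCohort:
    """Generate the base cohort: controls ~ N(0,1), disease DEGs mean-shifted,
    within-module correlation targeted at ``within_module_corr``."""
    rho = np.full(config.n_modules, config.within_module_corr)
    return _simulate(config, config.n_ra, config.n_control, rho, "base-noise", "base")


def generate_holdout(config: SimulationConfig, n_ra: int, n_control: int) -> ExpressionCohort:
    """Independently generated cohort with per-module correlation targets
    shifted by ``holdout_corr_shift`` to emulate a batch effect.

    The DEG effect map is identical to the base cohort's (same substream);
    only the correlation structure and the samples themselves are new.
    """
    if n_ra <= 0 or n_control <= 0:
        raise ConfigurationError("holdout class counts must be positive")
    shift_spec = config.holdout_corr_shift
    rng = substream(config.seed, "holdout-shift")
    if np.isscalar(shift_spec):
        shifts = np.full(config.n_modules, float(shift_spec))
    else:
        lo, hi = shift_spec
        shifts = rng.uniform(lo, hi, size=config.n_modules)
    rho = config.within_module_corr + shifts
    clipped = (rho <= 0.0) | (rho >= 1.0)
    if clipped.any():
        logger.warning(
            "holdout correlation target clamped to (0, 1) for %d modules", int(clipped.sum())
        )
        rho = np.clip(rho, 1e-3, 1.0 - 1e-3)
    return _simulate(config, n_ra, n_control, rho, "holdout-noise", "holdout")


def zscore_normalize(
    cohort: ExpressionCohort, reference: Optional[ExpressionCohort] = None
) -> ExpressionCohort:
    """Per-gene centring/scaling to mean 0, sd 1 (population sd).

    With ``reference`` given, its per-gene mean/sd are applied instead —
    the train-fitted scaler applied to test/holdout so no test-set statistics
    leak into normalisation.  Zero-variance genes map to all-zero columns.
    """
    ref = reference if reference is not None else cohort
    if reference is not None and not np.array_equal(reference.gene_ids, cohort.gene_ids):
        raise ValueError("reference cohort has a different gene universe")
    mean = ref.expression.mean(axis=0)
    sd = ref.expression.std(axis=0)
    degenerate = sd < 1e-12
    if degenerate.any():
        logger.warning("%d zero-variance genes; sd floored", int(degenerate.sum()))
    sd = np.where(degenerate, 1e-12, sd)
    z = (cohort.expression - mean) / sd
    z[:, degenerate] = 0.0
    out = replace_expression(cohort, z)
    out.provenance["normalized_against"] = ref.provenance.get("cohort_name", "self")
    return out


def replace_expression(cohort: ExpressionCohort, expression: np.ndarray) -> ExpressionCohort:
    return ExpressionCohort(
        expression=expression,
        labels=cohort.labels.copy(),
        gene_ids=cohort.gene_ids,
        true_module_of_gene=cohort.true_module_of_gene,
        deg_effect=cohort.deg_effect,
        provenance=dict(cohort.provenance),
    )


def stratified_split(
    cohort: ExpressionCohort,
    train_fraction: float = 0.7,
    target_counts: Optional[dict[int, int]] = None,
    seed: int = 0,
) -> SplitResult:
    """Deterministic stratified train/test split.

    ``target_counts`` maps label -> exact number of *training* samples for
    that class, overriding ``train_fraction`` (used to reproduce printed
    study counts that do not match a plain 70% split).
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = substream(seed, "split")
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for label in sorted(np.unique(cohort.labels)):
        members = np.flatnonzero(cohort.labels == label)
        if target_counts is not None:
            k = int(target_counts[int(label)])
            if k > members.size:
                raise ValueError(
                    f"target count {k} for class {label} exceeds available {members.size}"
                )
        else:
            k = int(round(train_fraction * members.size))
        if k <= 0 or k >= members.size:
            raise ValueError(f"split leaves class {label} empty in train or test")
        perm = rng.permutation(members)
        train_idx.append(np.sort(perm[:k]))
        test_idx.append(np.sort(perm[k:]))
    train = cohort.subset(np.concatenate(train_idx), name="train")
    test = cohort.subset(np.concatenate(test_idx), name="test")
    return SplitResult(train=train, test=test)
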