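"""Seeded generator of labeled two-subtype expression matrices.

Emulates the statistical shape of a bulk RNA-seq tumor-subtype cohort on the
log-TPM scale: a few hundred to a thousand samples, thousands of genes, two
classes with a minority fraction near 0.45, class-differential signal in a
subset of genes, and co-expressed gene blocks produced by shared latent
factors (pure i.i.d. features would make both distance preservation and
classification unrealistically easy).  Values are generated directly on the
log scale the pipeline consumes, clipped at 0; everything is determined by
the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .preprocess import ExpressionMatrix, LabelVector

MAJORITY_LABEL = "subtype_a"
MINORITY_LABEL = "subtype_b"


@dataclass
class SyntheticConfig:
    """Generator knobs.

    ``minority_fraction`` defaults to 0.45, the class balance of a typical
    two-subtype lung cohort; ``effect_size_delta`` is the mean log2 shift of
    signal genes between classes; ``block_strength`` is the latent-factor
    loading magnitude creating co-expression blocks; ``noise_sd`` the i.i.d.
    Gaussian noise level on the log scale.
    """

    n_samples: int = 300
    n_genes: int = 2000
    minority_fraction: float = 0.45
    n_signal_genes: int = 100
    effect_size_delta: float = 1.0
    n_coexpression_blocks: int = 10
    block_strength: float = 1.0
    noise_sd: float = 1.0
    base_mean_shape: float = 2.0   # gamma shape for per-gene baseline means
    base_mean_scale: float = 2.0   # gamma scale (mean 4 on the log2-TPM scale)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.minority_fraction < 1:
            raise ValueError("minority_fraction must be in (0, 1)")
        if self.n_signal_genes > self.n_genes:
            raise ValueError("n_signal_genes cannot exceed n_genes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_samples < 4 or self.n_genes < 1:
            raise ValueError("need n_samples >= 4 and n_genes >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def generate(cfg: SyntheticConfig):
    """Draw one labeled dataset.

    Returns ``(ExpressionMatrix stage=log, LabelVector, signal_gene_ids)``
    where the third element is the ground-truth set of class-differential
    genes (empty for a null configuration).
    """
    rng = np.random.default_rng(cfg.seed)
    n, d = cfg.n_samples, cfg.n_genes

    # class assignment: deterministic counts, order shuffled by seed
    n_minority = round(n * cfg.minority_fraction)
    y = np.array([1] * n_minority + [0] * (n - n_minority))
    rng.shuffle(y)

    mu = rng.gamma(cfg.base_mean_shape, cfg.base_mean_scale, size=d)

    # shared latent factors -> co-expressed gene blocks (low-rank structure)
    values = np.tile(mu, (n, 1))
    if cfg.n_coexpression_blocks > 0 and cfg.block_strength > 0:
        L = cfg.n_coexpression_blocks
        factors = rng.normal(size=(n, L))
        loadings = np.zeros((d, L))
        block_of = np.arange(d) % L
        loadings[np.arange(d), block_of] = cfg.block_strength * rng.uniform(0.5, 1.5, size=d)
        values = values + factors @ loadings.T

    signal_idx = np.array([], dtype=int)
    if cfg.n_signal_genes > 0 and cfg.effect_size_delta != 0:
        signal_idx = rng.choice(d, size=cfg.n_signal_genes, replace=False)
        shift = np.where(y == 1, cfg.effect_size_delta / 2, -cfg.effect_size_delta / 2)
        values[:, signal_idx] += shift[:, None]

    values += rng.normal(scale=cfg.noise_sd, size=(n, d))
    values = np.clip(values, 0.0, None)

    gene_ids = [f"gene_{j:05d}" for j in range(d)]
    sample_ids = [f"sample_{i:04d}" for i in range(n)]
    X = ExpressionMatrix(values=values, sample_ids=sample_ids, gene_ids=gene_ids, stage="log")
    labels = LabelVector(
        labels=[MINORITY_LABEL if c else MAJORITY_LABEL for c in y],
        label_set=[MAJORITY_LABEL, MINORITY_LABEL],
        positive_class=MINORITY_LABEL,
    )
    signal_genes = [gene_ids[j] for j in sorted(signal_idx)]
    return X, labels, signal_genes


def make_benchmark_suite(seed: int = 0) -> dict[str, SyntheticConfig]:
    """Fixed configurations used throughout the test benchmarks.

    - strong_signal: nearly separable classes (delta 2.0)
    - mid_signal: moderate effect (delta 0.8)
    - null: no class signal at all
    - high_dim_small_n: the d >> n regime that motivates random projection
    """
    return {
        "strong_signal": SyntheticConfig(
            n_samples=300, n_genes=2000, n_signal_genes=100, effect_size_delta=2.0, seed=seed
        ),
        "mid_signal": SyntheticConfig(
            n_samples=300, n_genes=2000, n_signal_genes=100, effect_size_delta=0.8, seed=seed
        ),
        "null": SyntheticConfig(
            n_samples=300, n_genes=2000, n_signal_genes=0, effect_size_delta=0.0, seed=seed
        ),
        "high_dim_small_n": SyntheticConfig(
            n_samples=120, n_genes=10000, n_signal_genes=100, effect_size_delta=2.0, seed=seed
        ),
    }
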