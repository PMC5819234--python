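"""Deterministic synthetic data with the structure the pipeline assumes.

Three generators, all pure functions of (parameters, seed):

* ``simulate_modular_expression`` — a Gaussian factor model: each
  planted module m has a latent per-sample factor f_m (standard normal
  plus an optional per-class activity shift), member genes are
  lambda * f_m + sigma * noise, and background genes are independent
  noise. Under this model the expected within-module gene correlation
  is lambda^2 / (lambda^2 + sigma^2), and the latent factor is the
  module's true eigengene — both give closed forms to test against.
* ``simulate_nb_counts`` — negative-binomial counts with a common
  dispersion alpha (variance mu + alpha*mu^2) and log-uniform gene
  means, for exercising the variance-stabilizing transform.
* ``simulate_interactions`` — Bernoulli edges with separate within- and
  between-module probabilities over a planted assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "simulate_modular_expression",
    "simulate_nb_counts",
    "simulate_interactions",
]


@dataclass
class SimulationConfig:
    """Factor-model simulation settings.

    class_shifts maps (module index, class label) to an additive shift
    of that module's latent factor in that class, in factor-sd units —
    the planted ground truth for class-specific module activity.
    """

    n_modules: int = 5
    genes_per_module: int = 50
    n_background_genes: int = 250
    samples_per_class: dict[str, int] = field(
        default_factory=lambda: {"control": 20, "disease": 20}
    )
    loading: float = 0.9
    noise_sd: float = 0.5
    class_shifts: dict[tuple[int, str], float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.loading < 0 or self.noise_sd < 0:
            raise ValueError("loading and noise_sd must be non-negative")


def simulate_modular_expression(
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Simulate a genes x samples matrix with planted co-expression modules.

    Returns (expression frame, truth assignment gene -> "M<i>" or
    "Uncorrelated", sample annotation sample -> class). Identical seeds
    give identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    classes: list[str] = []
    for cls, n in cfg.samples_per_class.items():
        classes.extend([cls] * n)
    n_samples = len(classes)
    sample_ids = [f"S{i + 1}" for i in range(n_samples)]
    annotation = pd.Series(classes, index=sample_ids, name="class")

    gene_ids, rows, truth = [], [], []
    for m in range(cfg.n_modules):
        factor = rng.standard_normal(n_samples)
        for j, cls in enumerate(classes):
            factor[j] += cfg.class_shifts.get((m, cls), 0.0)
        for g in range(cfg.genes_per_module):
            gene_ids.append(f"M{m + 1}G{g + 1}")
            truth.append(f"M{m + 1}")
            rows.append(cfg.loading * factor + cfg.noise_sd * rng.standard_normal(n_samples))
    for g in range(cfg.n_background_genes):
        gene_ids.append(f"BG{g + 1}")
        truth.append("Uncorrelated")
        rows.append(rng.standard_normal(n_samples))

    expr = pd.DataFrame(np.array(rows), index=gene_ids, columns=sample_ids)
    return expr, pd.Series(truth, index=gene_ids, name="module"), annotation


def simulate_nb_counts(
    n_genes: int,
    n_samples: int,
    mean_range: tuple[float, float] = (1.0, 1000.0),
    alpha: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Negative-binomial counts with variance mu + alpha*mu^2.

    Gene means are log-uniform over ``mean_range``; alpha = 0 gives the
    Poisson limit. Deterministic per seed.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    rng = np.random.default_rng(seed)
    lo, hi = mean_range
    mu = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_genes))
    if alpha == 0:
        counts = rng.poisson(mu[:, None], size=(n_genes, n_samples))
    else:
        # NB with mean mu and variance mu + alpha*mu^2:
        # n = 1/alpha successes, p = n/(n+mu)
        n = 1.0 / alpha
        p = n / (n + mu)
        counts = rng.negative_binomial(n, p[:, None], size=(n_genes, n_samples))
    return pd.DataFrame(
        counts.astype(float),
        index=[f"G{i + 1}" for i in range(n_genes)],
        columns=[f"S{j + 1}" for j in range(n_samples)],
    )


def simulate_interactions(
    truth: pd.Series,
    within_p: float,
    between_p: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Random undirected edges with module-dependent probabilities.

    Same-module gene pairs get an edge with probability ``within_p``,
    cross-module (or background) pairs with ``between_p``.
    """
    if not (0 <= within_p <= 1 and 0 <= between_p <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = list(truth.index)
    labels = truth.to_numpy()
    edges = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            same = labels[i] == labels[j] and labels[i] != "Uncorrelated"
            p = within_p if same else between_p
            if p > 0 and rng.random() < p:
                edges.append((genes[i], genes[j]))
    return pd.DataFrame(edges, columns=["gene_a", "gene_b"])
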