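"""Module-level functional enrichment.

Three analyses:

* **ORA** — per (module, gene set), the upper-tail hypergeometric
  probability of the observed overlap given the filtered-gene universe;
  Benjamini-Hochberg adjusted within each module across sets.
* **GSEA** — per (module, phenotype class), a preranked weighted
  Kolmogorov-Smirnov enrichment score treating the module's genes as
  the gene set and the class's mean z-score profile as the ranking;
  significance by permuting gene labels, with NES normalized by the
  mean same-sign permuted |ES|; BH adjusted across all module x class
  pairs.
* **CES** — the combined enrichment score condensing a run's ORA output
  into one number: the geometric mean over modules of each module's
  minimum adjusted p (lower = more enriched; 1 when nothing is
  enriched). This compact form honors the intended direction of the
  score; it is an approximation, not a reference formula.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ora",
    "class_rankings",
    "enrichment_score",
    "gsea",
    "combined_enrichment_score",
]

UNASSIGNED = "Uncorrelated"


def ora(
    assignment: pd.Series,
    gene_sets: dict[str, tuple[str, list[str]]],
    universe: list[str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of gene sets in each module.

    The universe defaults to all genes in the assignment (the filtered
    genes); gene sets are intersected with it and "Uncorrelated" genes
    form no module. p is P(X >= overlap) drawing |module| genes from the
    universe containing |set| successes; BH adjustment is applied within
    each module across sets. Rows are sorted by (module, adjusted p).
    """
    if universe is None:
        universe = list(assignment.index)
    uni = set(universe)
    n_uni = len(uni)
    modules = sorted(
        (l for l in pd.unique(assignment) if l != UNASSIGNED),
        key=lambda l: int(l[1:]) if str(l)[1:].isdigit() else 10**9,
    )
    rows = []
    for m in modules:
        mod_genes = set(assignment.index[assignment == m]) & uni
        block = []
        for name, (_desc, members) in gene_sets.items():
            set_genes = set(members) & uni
            if not set_genes:
                logger.info("gene set %r has no overlap with the universe; skipped", name)
                continue
            overlap = len(mod_genes & set_genes)
            # P(X >= overlap), X ~ Hypergeom(N=n_uni, K=|set|, n=|module|)
            p = float(stats.hypergeom.sf(overlap - 1, n_uni, len(set_genes), len(mod_genes)))
            block.append(
                {
                    "module": m,
                    "gene_set": name,
                    "overlap": overlap,
                    "module_size": len(mod_genes),
                    "set_size": len(set_genes),
                    "universe_size": n_uni,
                    "p": min(p, 1.0),
                }
            )
        if not block:
            continue
        bdf = pd.DataFrame(block)
        bdf["adj_p"] = multipletests(bdf["p"], method="fdr_bh")[1]
        rows.append(bdf.sort_values(["adj_p", "p", "gene_set"], kind="stable"))
    if not rows:
        return pd.DataFrame(
            columns=[
                "module", "gene_set", "overlap", "module_size",
                "set_size", "universe_size", "p", "adj_p",
            ]
        )
    return pd.concat(rows, ignore_index=True)


def class_rankings(expr: pd.DataFrame, annotation: pd.Series) -> pd.DataFrame:
    """Per-class gene scores: mean z-score over the class's samples.

    Each gene is z-scored across ALL samples first (mean 0, sd 1), then
    averaged within each phenotype class; because the z-scores sum to
    zero per gene, the class means are contrasts against the pooled
    baseline. Returns a genes x classes frame; classes with no samples
    are dropped with a warning.
    """
    annotation = annotation[annotation.index.isin(expr.columns)]
    X = expr.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    zdf = pd.DataFrame(z, index=expr.index, columns=expr.columns)
    cols = {}
    for cls in pd.unique(annotation):
        samples = annotation.index[annotation == cls]
        if len(samples) == 0:
            logger.warning("class %r has no samples; excluded", cls)
            continue
        cols[cls] = zdf[samples].mean(axis=1)
    return pd.DataFrame(cols)


def enrichment_score(
    scores: pd.Series, member_genes: set[str], weight: float = 1.0
) -> float:
    """Weighted KS enrichment score of a gene set against a ranking.

    Genes are ordered by decreasing score; hits advance the running sum
    proportionally to |score|^weight, misses retreat by 1/(N - N_hit).
    The ES is the running-sum extremum of largest magnitude. Requires
    the set to be a proper non-empty subset of the ranked genes.
    """
    order = scores.sort_values(ascending=False, kind="stable")
    is_hit = order.index.isin(member_genes)
    n_hit = int(is_hit.sum())
    n = len(order)
    if n_hit == 0:
        raise ValueError("gene set has no genes in the ranking")
    if n_hit == n:
        raise ValueError("gene set covers the whole ranking; ES undefined")
    w = np.abs(order.to_numpy()) ** weight
    hit_w = np.where(is_hit, w, 0.0)
    total_hit = hit_w.sum()
    if total_hit == 0:  # all member scores exactly 0: fall back to unweighted
        hit_w = is_hit.astype(float)
        total_hit = hit_w.sum()
    step = hit_w / total_hit - (~is_hit).astype(float) / (n - n_hit)
    running = np.cumsum(step)
    return float(running[np.argmax(np.abs(running))])


def gsea(
    rankings: pd.DataFrame,
    assignment: pd.Series,
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Preranked GSEA of every module against every class ranking.

    The null distribution permutes gene labels (``n_perm`` draws with
    the given seed, shared across all tests for reproducibility).
    Nominal p is the fraction of same-sign permuted ES with |ES| at
    least the observed |ES|; NES divides ES by the mean |permuted ES| of
    the same sign. BH adjustment spans all module x class pairs.
    """
    rng = np.random.default_rng(seed)
    modules = sorted(
        (l for l in pd.unique(assignment) if l != UNASSIGNED),
        key=lambda l: int(l[1:]) if str(l)[1:].isdigit() else 10**9,
    )
    rows = []
    gene_pool = [g for g in rankings.index]
    for m in modules:
        members = set(assignment.index[assignment == m]) & set(gene_pool)
        if len(members) < 2:
            logger.warning("module %s has <2 ranked genes; skipped in GSEA", m)
            continue
        size = len(members)
        # one permutation stream per module so results don't depend on
        # which other modules are present
        mod_rng = np.random.default_rng(rng.integers(2**31))
        perms = [
            set(mod_rng.choice(gene_pool, size=size, replace=False))
            for _ in range(n_perm)
        ]
        for cls in rankings.columns:
            scores = rankings[cls]
            es = enrichment_score(scores, members)
            null = np.array([enrichment_score(scores, p) for p in perms])
            same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
            if same_sign.size == 0:
                p = 1.0 / (n_perm + 1)
                nes = np.sign(es) * np.inf if es != 0 else 0.0
            else:
                p = (np.sum(np.abs(same_sign) >= abs(es)) + 1) / (same_sign.size + 1)
                denom = float(np.mean(np.abs(same_sign)))
                nes = es / denom if denom > 0 else 0.0
            rows.append(
                {"module": m, "class": cls, "es": es, "nes": float(nes),
                 "p": float(p), "size": size}
            )
    if not rows:
        return pd.DataFrame(columns=["module", "class", "es", "nes", "p", "size", "adj_p"])
    out = pd.DataFrame(rows)
    out["adj_p"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def combined_enrichment_score(ora_rows: pd.DataFrame) -> tuple[float, pd.Series]:
    """Condense ORA output into a single number (lower = more enriched).

    Per module, take the minimum BH-adjusted p (1 when the module has no
    rows); the score is the geometric mean of these minima over modules.
    Lies in (0, 1] and equals 1 when no module shows any enrichment.
    """
    if ora_rows.empty:
        return 1.0, pd.Series(dtype=float)
    minima = ora_rows.groupby("module")["adj_p"].min()
    minima = minima.clip(lower=np.finfo(float).tiny)
    ces = float(np.exp(np.mean(np.log(minima))))
    return ces, minima
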