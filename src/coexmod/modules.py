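"""Module detection on topological overlap, eigengenes, merging and hubs.

Genes are clustered by average-linkage hierarchical clustering on the
TOM dissimilarity 1 - TOM. The dendrogram is cut at a fixed fraction of
its top merge height (the "tree" variant of dynamic tree cutting);
branches with at least ``min_module_size`` members become modules and
everything else is labeled "Uncorrelated". A PAM-like refinement then
re-assigns each unlabeled gene to the module minimizing its average
dissimilarity, but only when that average beats the gene's average
dissimilarity to all non-module genes — so genuinely uncorrelated genes
stay unlabeled. Modules are renumbered M1..Mk by decreasing size.

A module eigengene is the first principal component of the module's
standardized expression, sign-oriented to correlate positively with the
module mean profile. Optional merging joins module pairs whose
eigengenes correlate above a threshold. Hub genes are ranked by
intramodular connectivity (sum of adjacency to other members).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array

logger = logging.getLogger(__name__)

__all__ = [
    "TomModuleDetector",
    "cluster_genes",
    "cut_modules",
    "module_eigengene",
    "merge_similar",
    "hub_genes",
]

UNASSIGNED = "Uncorrelated"


def cluster_genes(tom: np.ndarray) -> np.ndarray:
    """Average-linkage dendrogram on the dissimilarity 1 - TOM.

    Deterministic given its input; scipy breaks ties by lowest
    observation index.
    """
    tom = np.asarray(tom, dtype=float)
    if tom.shape[0] < 2:
        raise ValueError("need at least 2 genes to cluster")
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
    return hierarchy.linkage(squareform(diss, checks=False), method="average")


def _renumber(labels: pd.Series) -> pd.Series:
    """Renumber module labels M1..Mk by decreasing size (ties: first-seen order)."""
    named = labels[labels != UNASSIGNED]
    if named.empty:
        return labels
    sizes = named.value_counts()
    order = sorted(sizes.index, key=lambda l: (-sizes[l], str(l)))
    mapping = {old: f"M{i + 1}" for i, old in enumerate(order)}
    mapping[UNASSIGNED] = UNASSIGNED
    return labels.map(mapping)


def cut_modules(
    linkage: np.ndarray,
    dissimilarity: np.ndarray,
    min_module_size: int = 20,
    cut_height_fraction: float = 0.95,
    gene_ids: list[str] | None = None,
    refine: bool = True,
) -> pd.Series:
    """Cut the dendrogram into modules of at least ``min_module_size``.

    The static cut is placed at ``cut_height_fraction`` of the top merge
    height; branches that do not reach the size floor are labeled
    "Uncorrelated", optionally followed by the PAM-like refinement
    described in the module docstring. Returns a Series gene -> label.
    """
    n = dissimilarity.shape[0]
    if gene_ids is None:
        gene_ids = [str(i) for i in range(n)]
    if min_module_size > n:
        warnings.warn(
            f"min_module_size={min_module_size} exceeds gene count {n}; "
            "labeling all genes as uncorrelated"
        )
        return pd.Series(UNASSIGNED, index=gene_ids, name="module")

    heights = linkage[:, 2]
    cut_h = cut_height_fraction * float(heights.max()) if heights.max() > 0 else 0.0
    flat = hierarchy.fcluster(linkage, t=cut_h, criterion="distance")

    labels = pd.Series(UNASSIGNED, index=gene_ids, name="module", dtype=object)
    counts = pd.Series(flat).value_counts()
    next_id = 1
    for cl in counts.index:
        if counts[cl] >= min_module_size:
            labels.iloc[np.flatnonzero(flat == cl)] = f"tmp{next_id}"
            next_id += 1

    if refine and next_id > 1:
        labels = _trim_outliers(labels, dissimilarity, min_module_size)
        labels = _pam_refine(labels, dissimilarity)
    return _renumber(labels)


def _trim_outliers(labels: pd.Series, diss: np.ndarray, min_size: int) -> pd.Series:
    """Demote loosely attached members of each module to "Uncorrelated".

    A member is an outlier when its average dissimilarity to the rest of
    the module exceeds the Tukey fence (q75 + 1.5 IQR) of that statistic
    within the module — this strips background genes that merged into a
    tight branch just below the cut while leaving cohesive members
    alone. Modules are never trimmed below ``min_size``.
    """
    lab = labels.to_numpy(dtype=object).copy()
    for m in [l for l in pd.unique(lab) if l != UNASSIGNED]:
        idx = np.flatnonzero(lab == m)
        if len(idx) <= min_size:
            continue
        sub = diss[np.ix_(idx, idx)]
        avg = (sub.sum(axis=1)) / (len(idx) - 1)
        q25, q75 = np.percentile(avg, [25, 75])
        fence = q75 + 1.5 * (q75 - q25)
        outliers = idx[avg > fence]
        if len(idx) - len(outliers) < min_size:
            # keep the tightest min_size members
            order = idx[np.argsort(avg, kind="stable")]
            outliers = order[min_size:][avg[np.argsort(avg, kind="stable")][min_size:] > fence]
        lab[outliers] = UNASSIGNED
    return pd.Series(lab, index=labels.index, name="module")


def _pam_refine(labels: pd.Series, diss: np.ndarray) -> pd.Series:
    """Assign unlabeled genes to the nearest module when they look like members.

    A gene joins the module with smallest average dissimilarity only if
    (a) that average is below its average dissimilarity to all genes
    outside that module, and (b) it is no larger than the module's own
    average intramodular dissimilarity — so genes that are merely "least
    far" from every module (typical of uncorrelated background, which is
    nearly equidistant from everything) stay unassigned.
    """
    lab = labels.to_numpy(dtype=object).copy()
    module_names = [l for l in pd.unique(lab) if l != UNASSIGNED]
    unassigned = np.flatnonzero(lab == UNASSIGNED)
    members = {m: np.flatnonzero(lab == m) for m in module_names}
    intra = {}
    for m, idx in members.items():
        sub = diss[np.ix_(idx, idx)]
        n = len(idx)
        intra[m] = float(sub.sum() / (n * (n - 1))) if n > 1 else 0.0
    for g in unassigned:
        best, best_d = None, np.inf
        for m, idx in members.items():
            d = float(diss[g, idx].mean())
            if d < best_d:
                best, best_d = m, d
        if best is None or best_d > intra[best]:
            continue
        outside = np.flatnonzero(lab != best)
        outside = outside[outside != g]
        if outside.size and best_d < float(diss[g, outside].mean()):
            lab[g] = best
    return pd.Series(lab, index=labels.index, name="module")


def module_eigengene(
    expr: pd.DataFrame, assignment: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """First principal component per module, as a per-sample score.

    Each member gene is standardized across samples; the eigengene is
    the unit-norm first right singular vector of the member x sample
    matrix, sign-oriented so its correlation with the module mean
    profile is non-negative. Returns (eigengenes as module x sample
    frame, variance-explained fraction per module).
    """
    modules = [l for l in pd.unique(assignment) if l != UNASSIGNED]
    scores, varexp = {}, {}
    for m in modules:
        genes = assignment.index[assignment == m]
        sub = expr.loc[genes].to_numpy(dtype=float)
        sd = sub.std(axis=1, ddof=0)
        sd[sd == 0] = 1.0
        z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
        if z.shape[0] == 1:
            vec = z[0] / (np.linalg.norm(z[0]) or 1.0)
            ve = 1.0
        else:
            u, s, vt = np.linalg.svd(z, full_matrices=False)
            vec = vt[0]
            ve = float(s[0] ** 2 / np.sum(s**2))
        mean_profile = z.mean(axis=0)
        if np.dot(vec, mean_profile) < 0:
            vec = -vec
        scores[m] = vec
        varexp[m] = ve
    eig = pd.DataFrame(scores, index=expr.columns).T
    return eig, pd.Series(varexp, name="variance_explained")


def merge_similar(
    expr: pd.DataFrame,
    assignment: pd.Series,
    merge_threshold: float = 0.8,
) -> pd.Series:
    """Iteratively merge module pairs whose eigengene correlation exceeds
    ``merge_threshold`` (strict), recomputing eigengenes after each merge."""
    labels = assignment.copy()
    while True:
        eig, _ = module_eigengene(expr, labels)
        if eig.shape[0] < 2:
            break
        corr = np.corrcoef(eig.to_numpy())
        names = list(eig.index)
        best_pair, best_c = None, merge_threshold
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if corr[i, j] > best_c:
                    best_pair, best_c = (names[i], names[j]), corr[i, j]
        if best_pair is None:
            break
        a, b = best_pair
        logger.info("merging modules %s and %s (eigengene cor %.3f)", a, b, best_c)
        labels[labels == b] = a
    return _renumber(labels)


def hub_genes(
    adjacency: np.ndarray,
    assignment: pd.Series,
    top_n: int = 10,
) -> pd.DataFrame:
    """Top intramodular hubs per module.

    Connectivity of a member gene is its summed adjacency to the other
    members; ties break alphabetically by gene id. Returns a frame
    (module, rank, gene, connectivity).
    """
    gene_index = {g: i for i, g in enumerate(assignment.index)}
    rows = []
    modules = sorted(
        (l for l in pd.unique(assignment) if l != UNASSIGNED),
        key=lambda l: int(l[1:]) if str(l)[1:].isdigit() else 10**9,
    )
    for m in modules:
        genes = list(assignment.index[assignment == m])
        idx = np.array([gene_index[g] for g in genes])
        sub = adjacency[np.ix_(idx, idx)].copy()
        np.fill_diagonal(sub, 0.0)
        conn = sub.sum(axis=1)
        ranked = sorted(zip(genes, conn), key=lambda t: (-t[1], t[0]))[:top_n]
        for rank, (g, c) in enumerate(ranked, start=1):
            rows.append({"module": m, "rank": rank, "gene": g, "connectivity": float(c)})
    return pd.DataFrame(rows, columns=["module", "rank", "gene", "connectivity"])


class TomModuleDetector(ClusterMixin, BaseEstimator):
    """Cluster genes into co-expression modules from a precomputed TOM.

    ``fit(X)`` expects X to be the genes x genes topological overlap
    matrix. Fitted attributes: ``labels_`` (array of module labels, with
    "Uncorrelated" for unassigned genes) and ``linkage_``.

    Parameters
    ----------
    min_module_size : int, default 20
        Smallest branch that becomes a named module.
    cut_height_fraction : float, default 0.95
        Static cut height as a fraction of the top merge height.
    refine : bool, default True
        Apply the PAM-like re-assignment of unlabeled genes.
    """

    def __init__(
        self,
        min_module_size: int = 20,
        cut_height_fraction: float = 0.95,
        refine: bool = True,
    ):
        self.min_module_size = min_module_size
        self.cut_height_fraction = cut_height_fraction
        self.refine = refine

    def fit(self, X, y=None):
        X = check_array(X)
        if X.shape[0] != X.shape[1]:
            raise ValueError("expected a square TOM matrix")
        self.linkage_ = cluster_genes(X)
        labels = cut_modules(
            self.linkage_,
            1.0 - X,
            min_module_size=self.min_module_size,
            cut_height_fraction=self.cut_height_fraction,
            refine=self.refine,
        )
        self.labels_ = labels.to_numpy(dtype=object)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
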