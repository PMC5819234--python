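"""Readers and writers for the pipeline's tabular formats.

All tabular inputs are tab-separated text with a header row. Gene
identifiers are opaque, case-sensitive strings; no symbol mapping is
attempted. The in-memory containers are plain pandas objects:

* expression matrix — ``DataFrame`` with gene ids as the index and
  sample ids as columns (genes x samples);
* sample annotation — ``Series`` mapping sample id to phenotype class;
* gene-set collection — ``dict`` mapping set name to
  ``(description, list_of_genes)``;
* interaction table — ``DataFrame`` with columns ``gene_a``/``gene_b``
  holding a cleaned undirected edge list.
"""

from __future__ import annotations

import json
import logging
import os
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "read_annotation",
    "read_gmt",
    "read_interactions",
    "write_gmt",
    "write_results",
    "validate_expression",
]


def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Validate an in-memory genes x samples expression matrix.

    Enforces: unique gene and sample ids, all-finite numeric values,
    at least 2 genes and 2 samples. Returns the validated frame with a
    float dtype.
    """
    if expr.index.duplicated().any():
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dups[:5]}")
    if expr.columns.duplicated().any():
        dups = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dups[:5]}")
    if expr.shape[0] < 2 or expr.shape[1] < 2:
        raise ValueError(
            f"expression matrix must be at least 2 genes x 2 samples, got {expr.shape}"
        )
    values = expr.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("expression matrix contains non-numeric values")
    if not np.isfinite(values).all():
        bad = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            "non-finite value at gene "
            f"{expr.index[bad[0]]!r}, sample {expr.columns[bad[1]]!r}"
        )
    return expr.astype(float)


def read_expression(path: str | os.PathLike) -> pd.DataFrame:
    """Read a genes-as-rows / samples-as-columns TSV expression matrix.

    The first column holds gene ids and the header row holds sample ids.
    Duplicated gene ids are collapsed by keeping the row with the highest
    mean expression (logged). Missing or non-numeric cells are an error:
    imputation would silently change downstream correlations.
    """
    raw = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    if raw.shape[1] < 2:
        raise ValueError(f"expression file {path} has <2 sample columns")
    try:
        # astype(float) is a correctly-rounded parse (exact TSV round-trips)
        expr = raw.astype(float)
    except (ValueError, TypeError):
        expr = None
    if expr is None or expr.isna().to_numpy().any():
        # locate the offending cell for a precise message
        for col in raw.columns:
            converted = pd.to_numeric(raw[col], errors="coerce")
            bad = converted.isna() | ~np.isfinite(converted)
            if bad.any():
                gene = raw.index[bad.to_numpy()][0]
                raise ValueError(
                    f"non-numeric or missing value at gene {gene!r}, "
                    f"sample {col!r} in {path}"
                )
        raise ValueError(f"could not parse numeric values in {path}")
    if expr.index.duplicated().any():
        n_before = expr.shape[0]
        means = expr.mean(axis=1)
        order = means.to_numpy()
        # stable sort descending by mean, keep the first occurrence of each id
        idx = np.argsort(-order, kind="stable")
        expr = expr.iloc[idx]
        expr = expr[~expr.index.duplicated(keep="first")]
        logger.info(
            "collapsed %d duplicated gene rows by keeping the highest-mean row",
            n_before - expr.shape[0],
        )
    return validate_expression(expr)


def read_annotation(path: str | os.PathLike, expr: pd.DataFrame | None = None) -> pd.Series:
    """Read a sample annotation TSV (columns: sample id, phenotype class).

    When ``expr`` is given, every annotated sample must exist in the
    expression matrix. Returns a Series indexed by sample id.
    """
    tab = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if tab.shape[1] < 2:
        raise ValueError(f"annotation file {path} needs >=2 columns (sample, class)")
    ann = pd.Series(
        tab.iloc[:, 1].to_numpy(), index=tab.iloc[:, 0].astype(str), name="class"
    )
    if ann.index.duplicated().any():
        dups = ann.index[ann.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated sample ids in annotation: {dups[:5]}")
    if ann.isna().any():
        raise ValueError("missing class labels in annotation")
    if expr is not None:
        unknown = ann.index.difference(expr.columns)
        if len(unknown) > 0:
            raise ValueError(
                f"annotated samples absent from expression matrix: {sorted(unknown)[:5]}"
            )
    return ann


def read_gmt(path: str | os.PathLike) -> dict[str, tuple[str, list[str]]]:
    """Read a GMT gene-set file: name TAB description TAB gene1 TAB gene2 ...

    Trailing empty fields are dropped; member lists are deduplicated
    preserving order. Duplicate set names or lines with fewer than three
    fields raise an error naming the line.
    """
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            while fields and fields[-1] == "":
                fields.pop()
            if len(fields) < 3:
                raise ValueError(
                    f"GMT line {lineno} has {len(fields)} fields; "
                    "expected name, description and >=1 gene"
                )
            name, desc, *genes = fields
            if name in sets:
                raise ValueError(f"duplicate gene-set name {name!r} at line {lineno}")
            members = list(dict.fromkeys(g for g in genes if g != ""))
            if not members:
                raise ValueError(f"gene set {name!r} at line {lineno} is empty")
            sets[name] = (desc, members)
    return sets


def write_gmt(sets: Mapping[str, tuple[str, list[str]]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, (desc, genes) in sets.items():
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_interactions(
    path: str | os.PathLike, known_genes: set[str] | None = None
) -> pd.DataFrame:
    """Read a two-column undirected gene-gene interaction edge list.

    A header row is auto-detected: the first row is treated as a header
    when neither of its first two fields matches a known expression gene
    (the ambiguity is logged). Self-loops are removed and duplicate
    edges collapsed regardless of endpoint order. An empty file yields
    an empty table with a warning rather than an error.
    """
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"interaction line needs >=2 columns: {line!r}")
            rows.append([fields[0], fields[1]])
    if not rows:
        logger.warning("interaction file %s is empty", path)
        return pd.DataFrame(columns=["gene_a", "gene_b"])
    start = 0
    if known_genes is not None:
        first = rows[0]
        if first[0] not in known_genes and first[1] not in known_genes:
            logger.info(
                "treating first interaction row %r as a header "
                "(neither field matches an expression gene)",
                first,
            )
            start = 1
    seen: set[frozenset[str]] = set()
    edges: list[tuple[str, str]] = []
    for a, b in rows[start:]:
        if a == b:
            continue
        key = frozenset((a, b))
        if key in seen:
            continue
        seen.add(key)
        edges.append((min(a, b), max(a, b)))
    if not edges:
        logger.warning("interaction file %s has no usable edges", path)
    return pd.DataFrame(edges, columns=["gene_a", "gene_b"])


def write_results(products: Mapping[str, object], out_dir: str | os.PathLike) -> dict:
    """Write every pipeline product as TSV/GMT/JSON and return a manifest.

    ``products`` maps product names to objects:

    ``assignment``  Series gene -> module label (required)
    ``filter``      FilterResult-like DataFrame (gene, mean, variance, p, selected)
    ``beta_curve``  DataFrame (beta, r2, mean_connectivity)
    ``summary``     dict of run parameters and selected values
    ``ora``         DataFrame of ORA rows (optional)
    ``gsea``        DataFrame of GSEA rows (optional)
    ``hubs``        DataFrame (module, rank, gene, connectivity) (optional)
    ``graphs``      dict module -> (nodes DataFrame, edges DataFrame) (optional)

    Column order is fixed so re-runs with the same inputs are
    byte-identical. Fails before any partial write when the directory is
    not writable.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    if not os.access(out_dir, os.W_OK):
        raise OSError(f"output directory {out_dir} is not writable")
    manifest: dict[str, str] = {}

    def _path(name: str) -> str:
        return os.path.join(out_dir, name)

    assignment: pd.Series = products["assignment"]  # type: ignore[assignment]
    adf = pd.DataFrame({"gene": assignment.index, "module": assignment.to_numpy()})
    adf.to_csv(_path("modules.tsv"), sep="\t", index=False)
    manifest["modules"] = "modules.tsv"

    module_sets = {
        label: (label, sorted(assignment.index[assignment == label]))
        for label in sorted(
            (l for l in assignment.unique() if l != "Uncorrelated"),
            key=lambda l: int(l[1:]) if l[1:].isdigit() else 10**9,
        )
    }
    write_gmt(module_sets, _path("modules.gmt"))
    manifest["modules_gmt"] = "modules.gmt"

    if "filter" in products and products["filter"] is not None:
        fdf: pd.DataFrame = products["filter"]  # type: ignore[assignment]
        fdf.to_csv(_path("gene_filter.tsv"), sep="\t", index=False)
        manifest["gene_filter"] = "gene_filter.tsv"

    if "beta_curve" in products and products["beta_curve"] is not None:
        bdf: pd.DataFrame = products["beta_curve"]  # type: ignore[assignment]
        bdf[["beta", "r2", "mean_connectivity"]].to_csv(
            _path("beta_curve.tsv"), sep="\t", index=False
        )
        manifest["beta_curve"] = "beta_curve.tsv"

    if "ora" in products and products["ora"] is not None:
        products["ora"].to_csv(_path("ora.tsv"), sep="\t", index=False)  # type: ignore[union-attr]
        manifest["ora"] = "ora.tsv"

    if "gsea" in products and products["gsea"] is not None:
        products["gsea"].to_csv(_path("gsea.tsv"), sep="\t", index=False)  # type: ignore[union-attr]
        manifest["gsea"] = "gsea.tsv"

    if "hubs" in products and products["hubs"] is not None:
        products["hubs"].to_csv(_path("hubs.tsv"), sep="\t", index=False)  # type: ignore[union-attr]
        manifest["hubs"] = "hubs.tsv"

    if "graphs" in products and products["graphs"] is not None:
        gdir = _path("interactions")
        os.makedirs(gdir, exist_ok=True)
        for label, (nodes, edges) in products["graphs"].items():  # type: ignore[union-attr]
            nodes.to_csv(os.path.join(gdir, f"{label}_nodes.tsv"), sep="\t", index=False)
            edges.to_csv(os.path.join(gdir, f"{label}_edges.tsv"), sep="\t", index=False)
            manifest[f"graph_{label}_nodes"] = f"interactions/{label}_nodes.tsv"
            manifest[f"graph_{label}_edges"] = f"interactions/{label}_edges.tsv"

    summary = dict(products.get("summary") or {})
    with open(_path("summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    manifest["summary"] = "summary.json"

    with open(_path("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
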