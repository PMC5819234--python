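"""End-to-end orchestration: expression in, modules + enrichment + report out.

Mirrors the single-command design: the expression matrix is the only
required input; annotation, gene sets and interactions each unlock an
optional stage (GSEA, ORA, interactome graphs). Stages communicate via
the containers defined in :mod:`coexmod.io`, so each stage can also be
run standalone from serialized intermediates.
"""

from __future__ import annotations

import logging
import shutil
import tempfile
import os
from dataclasses import dataclass, field, asdict
from typing import Any

import pandas as pd

from . import io as cio
from .filtering import FilterConfig, estimate_dispersion_and_vst, filter_genes
from .network import SoftThresholdNetwork
from .modules import TomModuleDetector, hub_genes, merge_similar, module_eigengene
from .enrichment import class_rankings, combined_enrichment_score, gsea, ora
from .interactome import module_interaction_graph

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Every knob of the pipeline, with the tool's defaults."""

    filter_pval: float = 0.1
    low_mean_fraction: float = 0.25
    apply_vst: bool = False
    network_type: str = "unsigned"
    cor_method: str = "pearson"
    beta_min: int = 1
    beta_max: int = 20
    tau: float = 0.8
    epsilon: float = 0.1
    force_beta: int | None = None
    min_module_size: int = 20
    merge_similar: bool = False
    merge_threshold: float = 0.8
    gsea_permutations: int = 1000
    seed: int | None = None
    make_report: bool = True
    extra: dict[str, Any] = field(default_factory=dict)


@dataclass
class PipelineResult:
    """In-memory bundle of every pipeline product."""

    expression: pd.DataFrame
    filter_table: pd.DataFrame
    beta_curve: pd.DataFrame
    selected_beta: int
    phi: float
    assignment: pd.Series
    eigengenes: pd.DataFrame
    variance_explained: pd.Series
    hubs: pd.DataFrame
    summary: dict
    ora_table: pd.DataFrame | None = None
    gsea_table: pd.DataFrame | None = None
    ces: float | None = None
    graphs: dict | None = None
    annotation: pd.Series | None = None


def run_pipeline(
    expr: pd.DataFrame,
    cfg: RunConfig | None = None,
    annotation: pd.Series | None = None,
    gene_sets: dict | None = None,
    interactions: pd.DataFrame | None = None,
    out_dir: str | None = None,
) -> PipelineResult:
    """Run filter -> soft-threshold -> modules -> enrichment -> outputs.

    ``expr`` is a validated genes x samples frame. Optional inputs each
    enable their stage independently; skipped stages are logged. When
    ``out_dir`` is given, all products (and the HTML report unless
    disabled) are written there atomically — nothing is left behind on
    error.
    """
    cfg = cfg or RunConfig()
    expr = cio.validate_expression(expr)
    summary: dict[str, Any] = {
        "n_genes_input": int(expr.shape[0]),
        "n_samples": int(expr.shape[1]),
        "parameters": {
            k: v for k, v in asdict(cfg).items() if k != "extra"
        },
        "seed": cfg.seed,
    }

    if cfg.apply_vst:
        expr, alpha = estimate_dispersion_and_vst(expr)
        summary["vst_alpha"] = alpha
        logger.info("VST applied with estimated dispersion alpha=%.4g", alpha)

    ftab = filter_genes(expr, FilterConfig(cfg.filter_pval, cfg.low_mean_fraction))
    selected = ftab.loc[ftab["selected"], "gene"].tolist()
    summary["n_genes_selected"] = len(selected)
    if len(selected) < 3:
        raise RuntimeError(
            f"only {len(selected)} genes pass the variance filter; "
            "relax --filter-pval or --low-mean-fraction"
        )
    fexpr = expr.loc[selected]

    net = SoftThresholdNetwork(
        beta_min=cfg.beta_min,
        beta_max=cfg.beta_max,
        tau=cfg.tau,
        epsilon=cfg.epsilon,
        network_type=cfg.network_type,
        correlation=cfg.cor_method,
        force_beta=cfg.force_beta,
    ).fit(fexpr.to_numpy().T)
    summary.update(
        selected_beta=net.beta_, phi=net.phi_,
        tau=cfg.tau, epsilon=cfg.epsilon, network_type=cfg.network_type,
    )

    detector = TomModuleDetector(min_module_size=cfg.min_module_size).fit(net.tom_)
    assignment = pd.Series(detector.labels_, index=fexpr.index, name="module")
    if cfg.merge_similar and assignment[assignment != "Uncorrelated"].nunique() >= 2:
        assignment = merge_similar(fexpr, assignment, cfg.merge_threshold)
    n_modules = int(assignment[assignment != "Uncorrelated"].nunique())
    summary["n_modules"] = n_modules
    if n_modules == 0:
        logger.warning("no modules found; downstream analyses will be empty")

    eig, varexp = (
        module_eigengene(fexpr, assignment)
        if n_modules
        else (pd.DataFrame(), pd.Series(dtype=float))
    )
    hubs = hub_genes(net.adjacency_, assignment)

    result = PipelineResult(
        expression=expr,
        filter_table=ftab,
        beta_curve=net.curve_,
        selected_beta=net.beta_,
        phi=net.phi_,
        assignment=assignment,
        eigengenes=eig,
        variance_explained=varexp,
        hubs=hubs,
        summary=summary,
        annotation=annotation,
    )

    if gene_sets is not None and n_modules:
        result.ora_table = ora(assignment, gene_sets)
        result.ces, _ = combined_enrichment_score(result.ora_table)
        summary["ces"] = result.ces
    else:
        logger.info("ORA skipped (no gene sets provided or no modules)")

    if annotation is not None and n_modules:
        ann = annotation[annotation.index.isin(expr.columns)]
        rankings = class_rankings(fexpr, ann)
        result.gsea_table = gsea(
            rankings, assignment, n_perm=cfg.gsea_permutations, seed=cfg.seed
        )
    else:
        logger.info("GSEA skipped (no annotation provided or no modules)")

    if interactions is not None and n_modules:
        result.graphs = module_interaction_graph(assignment, interactions)
    else:
        logger.info("interactome stage skipped (no interactions or no modules)")

    if out_dir is not None:
        _write_all(result, cfg, out_dir)
    return result


def _write_all(result: PipelineResult, cfg: RunConfig, out_dir: str) -> None:
    """Write all products (and the report) via a temp dir, then move into place."""
    parent = os.path.dirname(os.path.abspath(out_dir)) or "."
    os.makedirs(parent, exist_ok=True)
    tmp = tempfile.mkdtemp(prefix=".coexmod_", dir=parent)
    try:
        products = {
            "assignment": result.assignment,
            "filter": result.filter_table,
            "beta_curve": result.beta_curve,
            "summary": result.summary,
            "ora": result.ora_table,
            "gsea": result.gsea_table,
            "hubs": result.hubs,
            "graphs": result.graphs,
        }
        cio.write_results(products, tmp)
        if cfg.make_report:
            from .report import render_report

            render_report(result, tmp)
        os.makedirs(out_dir, exist_ok=True)
        for name in os.listdir(tmp):
            dest = os.path.join(out_dir, name)
            if os.path.isdir(dest):
                shutil.rmtree(dest)
            elif os.path.exists(dest):
                os.remove(dest)
            shutil.move(os.path.join(tmp, name), dest)
    finally:
        shutil.rmtree(tmp, ignore_errors=True)
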