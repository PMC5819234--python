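"""Static HTML report: one self-contained page plus an SVG figure per plot.

The report is a *view*: every number shown comes straight from the
tables the pipeline already wrote, nothing is recomputed. Optional
sections (ORA, GSEA, interactome) degrade to an explanatory stub when
their input was not provided. Rendering is deterministic — figure
hashing is salted and SVG timestamps stripped — so re-rendering the
same bundle is byte-identical.
"""

from __future__ import annotations

import os

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from jinja2 import Template

__all__ = ["render_report"]

MAX_PROFILE_LINES = 200  # gene lines per profile plot; mean stays exact over all

_SAVEFIG_KW = {"metadata": {"Date": None}, "format": "svg"}

_TEMPLATE = Template(
    """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>Co-expression module report</title>
<style>
body { font-family: sans-serif; margin: 2em auto; max-width: 1000px; }
table { border-collapse: collapse; margin: 1em 0; }
th, td { border: 1px solid #999; padding: 3px 8px; font-size: 90%; }
h2 { border-bottom: 2px solid #444; }
.stub { color: #777; font-style: italic; }
img { max-width: 100%; }
</style></head><body>
<h1>Co-expression module analysis</h1>

<h2>Run summary</h2>
<table>
{% for k, v in summary_rows %}<tr><th>{{ k }}</th><td>{{ v }}</td></tr>
{% endfor %}
</table>

<h2>Soft-threshold selection</h2>
<p>Scale-free fit R&sup2; per soft-threshold &beta;; selected &beta; = {{ beta }},
&phi; = {{ phi }}.</p>
<img src="figures/beta_curve.svg" alt="beta curve">

<h2>Module expression profiles</h2>
{% if profile_figs %}{% for m, fig in profile_figs %}
<h3>{{ m }}</h3><img src="figures/{{ fig }}" alt="profile {{ m }}">
{% endfor %}{% else %}
<p class="stub">No modules were detected; the report covers filtering and
soft-threshold selection only.</p>
{% endif %}

<h2>Over-representation analysis</h2>
{% if ora_figs %}
<p>Bars show &minus;log<sub>10</sub> adjusted p per gene set; the dashed line
marks adjusted p = 0.01.</p>
{% for m, fig in ora_figs %}<h3>{{ m }}</h3><img src="figures/{{ fig }}" alt="ORA {{ m }}">
{% endfor %}
{{ ora_table }}
{% else %}<p class="stub">No gene-set collection was provided; ORA skipped.</p>
{% endif %}

<h2>Gene set enrichment by phenotype</h2>
{% if gsea_fig %}
<p>Normalized enrichment score of each module in each sample class.</p>
<img src="figures/{{ gsea_fig }}" alt="GSEA heatmap">
{{ gsea_table }}
{% else %}<p class="stub">No sample annotation was provided; GSEA skipped.</p>
{% endif %}

<h2>Interaction networks</h2>
{% if graph_figs %}
<p>Module members are blue, interaction-file additions red; node size is
proportional to degree and the top hubs are labeled.</p>
{% for m, fig in graph_figs %}<h3>{{ m }}</h3><img src="figures/{{ fig }}" alt="network {{ m }}">
{% endfor %}
{% else %}<p class="stub">No interaction file was provided; network drawings skipped.</p>
{% endif %}

<h2>Module assignment</h2>
{{ assignment_table }}

</body></html>
"""
)


def _setup_determinism():
    plt.rcdefaults()
    matplotlib.rcParams["svg.hashsalt"] = "coexmod"


def _fig_beta_curve(curve: pd.DataFrame, beta: int, fig_dir: str) -> None:
    fig, ax1 = plt.subplots(figsize=(6, 4))
    ax1.plot(curve["beta"], curve["r2"], "o-", color="black")
    ax1.axvline(beta, color="red", linestyle="--", label=f"selected beta = {beta}")
    ax1.set_xlabel("soft-threshold beta")
    ax1.set_ylabel("scale-free fit R^2")
    ax1.set_ylim(-1.05, 1.05)
    ax1.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(os.path.join(fig_dir, "beta_curve.svg"), **_SAVEFIG_KW)
    plt.close(fig)


def _fig_profile(
    expr: pd.DataFrame, genes: list[str], annotation: pd.Series | None,
    path: str,
) -> None:
    sub = expr.loc[genes]
    z = sub.sub(sub.mean(axis=1), axis=0)
    sd = sub.std(axis=1, ddof=0).replace(0, 1.0)
    z = z.div(sd, axis=0)
    fig, ax = plt.subplots(figsize=(7, 3.2))
    shown = genes[:MAX_PROFILE_LINES]
    x = np.arange(z.shape[1])
    for g in shown:
        ax.plot(x, z.loc[g], color="#bbbbbb", linewidth=0.5)
    ax.plot(x, z.mean(axis=0), color="black", linewidth=2, label="module mean")
    if annotation is not None:
        classes = sorted(annotation.unique())
        cmap = plt.get_cmap("tab10")
        for i, cls in enumerate(classes):
            idx = [j for j, s in enumerate(z.columns) if annotation.get(s) == cls]
            ax.scatter(
                [x[j] for j in idx], [z.mean(axis=0).iloc[j] for j in idx],
                color=cmap(i), s=12, zorder=3, label=str(cls),
            )
    ax.set_xlabel("sample")
    ax.set_ylabel("standardized expression")
    ax.legend(loc="upper right", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, **_SAVEFIG_KW)
    plt.close(fig)


def _fig_ora(block: pd.DataFrame, path: str, top: int = 10) -> None:
    block = block.nsmallest(top, "adj_p").iloc[::-1]
    vals = -np.log10(block["adj_p"].clip(lower=np.finfo(float).tiny))
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(block) + 1.2))
    ax.barh(block["gene_set"], vals, color="#4477aa")
    ax.axvline(-np.log10(0.01), color="grey", linestyle="--")
    ax.set_xlabel("-log10 adjusted p")
    fig.tight_layout()
    fig.savefig(path, **_SAVEFIG_KW)
    plt.close(fig)


def _fig_gsea(gsea: pd.DataFrame, path: str) -> None:
    mat = gsea.pivot(index="module", columns="class", values="nes")
    fig, ax = plt.subplots(figsize=(1.2 * mat.shape[1] + 2, 0.5 * mat.shape[0] + 1.5))
    vmax = np.nanmax(np.abs(mat.to_numpy())) or 1.0
    im = ax.imshow(mat.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(mat.shape[1]), mat.columns)
    ax.set_yticks(range(mat.shape[0]), mat.index)
    fig.colorbar(im, ax=ax, label="NES")
    fig.tight_layout()
    fig.savefig(path, **_SAVEFIG_KW)
    plt.close(fig)


def _fig_graph(nodes: pd.DataFrame, edges: pd.DataFrame, path: str) -> None:
    import networkx as nx

    g = nx.Graph()
    for row in nodes.itertuples(index=False):
        g.add_node(row.gene, origin=row.origin, degree=row.degree, labeled=row.labeled)
    g.add_edges_from(edges.itertuples(index=False))
    pos = nx.spring_layout(g, seed=0)
    fig, ax = plt.subplots(figsize=(6, 5))
    colors = [
        "#4477aa" if g.nodes[n]["origin"] == "module" else "#cc3311" for n in g.nodes
    ]
    sizes = [30 + 20 * g.nodes[n]["degree"] for n in g.nodes]
    nx.draw_networkx_edges(g, pos, ax=ax, alpha=0.3)
    nx.draw_networkx_nodes(g, pos, ax=ax, node_color=colors, node_size=sizes)
    nx.draw_networkx_labels(
        g, pos, ax=ax, font_size=7,
        labels={n: n for n in g.nodes if g.nodes[n]["labeled"]},
    )
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, **_SAVEFIG_KW)
    plt.close(fig)


def _html_table(df: pd.DataFrame, max_rows: int = 200) -> str:
    if df is None or df.empty:
        return "<p class='stub'>(empty table)</p>"
    shown = df.head(max_rows)
    note = (
        f"<p class='stub'>showing first {max_rows} of {len(df)} rows "
        "(full table in the TSV output)</p>"
        if len(df) > max_rows
        else ""
    )
    return shown.to_html(index=False, border=0) + note


def render_report(result, out_dir: str) -> str:
    """Render the HTML report for a :class:`~coexmod.pipeline.PipelineResult`.

    Returns the path of the written ``report.html``; figures go under
    ``figures/``.
    """
    _setup_determinism()
    fig_dir = os.path.join(out_dir, "figures")
    os.makedirs(fig_dir, exist_ok=True)

    _fig_beta_curve(result.beta_curve, result.selected_beta, fig_dir)

    assignment = result.assignment
    modules = sorted(
        (l for l in assignment.unique() if l != "Uncorrelated"),
        key=lambda l: int(l[1:]) if str(l)[1:].isdigit() else 10**9,
    )
    profile_figs = []
    for m in modules:
        genes = list(assignment.index[assignment == m])
        name = f"profile_{m}.svg"
        _fig_profile(result.expression, genes, result.annotation, os.path.join(fig_dir, name))
        profile_figs.append((m, name))

    ora_figs = []
    ora_table_html = ""
    if result.ora_table is not None and not result.ora_table.empty:
        for m in modules:
            block = result.ora_table[result.ora_table["module"] == m]
            if block.empty:
                continue
            name = f"ora_{m}.svg"
            _fig_ora(block, os.path.join(fig_dir, name))
            ora_figs.append((m, name))
        ora_table_html = _html_table(result.ora_table)

    gsea_fig = None
    gsea_table_html = ""
    if result.gsea_table is not None and not result.gsea_table.empty:
        gsea_fig = "gsea_heatmap.svg"
        _fig_gsea(result.gsea_table, os.path.join(fig_dir, gsea_fig))
        gsea_table_html = _html_table(result.gsea_table)

    graph_figs = []
    if result.graphs:
        for m, (nodes, edges) in result.graphs.items():
            if nodes.empty:
                continue
            name = f"network_{m}.svg"
            _fig_graph(nodes, edges, os.path.join(fig_dir, name))
            graph_figs.append((m, name))

    summary = dict(result.summary)
    params = summary.pop("parameters", {})
    summary_rows = sorted(summary.items()) + sorted(
        (f"param: {k}", v) for k, v in params.items()
    )

    html = _TEMPLATE.render(
        summary_rows=summary_rows,
        beta=result.selected_beta,
        phi=f"{result.phi:.3f}",
        profile_figs=profile_figs,
        ora_figs=ora_figs,
        ora_table=ora_table_html,
        gsea_fig=gsea_fig,
        gsea_table=gsea_table_html,
        graph_figs=graph_figs,
        assignment_table=_html_table(
            pd.DataFrame({"gene": assignment.index, "module": assignment.to_numpy()})
        ),
    )
    out_path = os.path.join(out_dir, "report.html")
    with open(out_path, "w") as fh:
        fh.write(html)
    return out_path
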