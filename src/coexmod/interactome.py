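"""Per-module interaction subnetworks for display.

Given an undirected gene-gene interaction table (e.g. protein-protein
interactions), each module gets the subgraph of interactions touching
at least one module member. Non-member endpoints are kept with origin
"interaction_added" (one-hop expansion only); member nodes carry origin
"module". Node degree is counted on the resulting graph, and the
``top_n_labels`` highest-degree nodes are flagged for labeling in the
report. This display degree is distinct from the adjacency-based
intramodular hub connectivity; both are reported under their own names.
"""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["module_interaction_graph"]

UNASSIGNED = "Uncorrelated"


def module_interaction_graph(
    assignment: pd.Series,
    interactions: pd.DataFrame,
    top_n_labels: int = 10,
) -> dict[str, tuple[pd.DataFrame, pd.DataFrame]]:
    """Build one interaction subgraph per module.

    Returns, per module label, a pair of frames: nodes
    (gene, origin, degree, labeled) and edges (gene_a, gene_b). Modules
    untouched by any interaction yield empty frames (kept and logged).
    """
    modules = sorted(
        (l for l in pd.unique(assignment) if l != UNASSIGNED),
        key=lambda l: int(l[1:]) if str(l)[1:].isdigit() else 10**9,
    )
    out: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
    for m in modules:
        members = set(assignment.index[assignment == m])
        g = nx.Graph()
        for a, b in interactions[["gene_a", "gene_b"]].itertuples(index=False):
            if a in members or b in members:
                g.add_edge(a, b)
        if g.number_of_edges() == 0:
            logger.info("module %s has no touching interactions", m)
            out[m] = (
                pd.DataFrame(columns=["gene", "origin", "degree", "labeled"]),
                pd.DataFrame(columns=["gene_a", "gene_b"]),
            )
            continue
        degrees = dict(g.degree())
        ranked = sorted(degrees, key=lambda n: (-degrees[n], n))
        labeled = set(ranked[:top_n_labels])
        nodes = pd.DataFrame(
            {
                "gene": ranked,
                "origin": [
                    "module" if n in members else "interaction_added" for n in ranked
                ],
                "degree": [degrees[n] for n in ranked],
                "labeled": [n in labeled for n in ranked],
            }
        )
        edges = pd.DataFrame(
            sorted((min(a, b), max(a, b)) for a, b in g.edges()),
            columns=["gene_a", "gene_b"],
        )
        out[m] = (nodes, edges)
    return out
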