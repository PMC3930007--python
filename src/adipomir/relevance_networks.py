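"""Relevance networks: signed Pearson edges above an R² threshold.

Two miRNAs are connected when the squared Pearson correlation of their
expression across samples reaches the threshold (inclusive, default 0.95).
Negative correlations qualify too; the sign travels with the edge.  The
"networks" are the connected components (size ≥ 2) of the edge graph —
components, not cliques, since chained co-expression is what the method
reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_R2_THRESHOLD = 0.95


@dataclass(frozen=True)
class Edge:
    node_a: str
    node_b: str
    r: float

    @property
    def sign(self) -> str:
        return "+" if self.r >= 0 else "-"


@dataclass
class RelevanceNetwork:
    nodes: list[str]
    edges: list[Edge]
    components: list[list[str]]  # size ≥ 2, ordered by size desc then name
    r2_threshold: float
    node_attrs: dict[str, dict] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "r2_threshold": self.r2_threshold,
            "n_nodes": len(self.nodes),
            "n_edges": len(self.edges),
            "components": [list(c) for c in self.components],
        }

    def edge_tuples(self) -> list[tuple[str, str, float]]:
        return [(e.node_a, e.node_b, e.r) for e in self.edges]


# ---------------------------------------------------------------------------

def correlation_matrix(data: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise Pearson R between rows (miRNAs) across columns (samples).

    Rows with zero variance carry no correlation signal; they are excluded
    with a warning and returned separately.
    """
    if data.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlations")
    variances = data.var(axis=1, ddof=1)
    excluded = list(data.index[(variances == 0) | variances.isna()])
    if excluded:
        logger.warning("excluding zero-variance row(s): %s", excluded)
    kept = data.drop(index=excluded)
    r = np.corrcoef(kept.to_numpy())
    r = np.atleast_2d(r)
    np.fill_diagonal(r, 1.0)
    frame = pd.DataFrame(r, index=kept.index, columns=kept.index)
    return frame, excluded


def build_network(r_matrix: pd.DataFrame,
                  r2_threshold: float = DEFAULT_R2_THRESHOLD,
                  ) -> RelevanceNetwork:
    """Threshold the correlation matrix and extract connected components."""
    if not np.allclose(r_matrix.to_numpy(), r_matrix.to_numpy().T,
                       equal_nan=True):
        raise ValueError("correlation matrix must be symmetric")
    names = list(r_matrix.index)
    values = r_matrix.to_numpy()
    graph = nx.Graph()
    graph.add_nodes_from(names)
    edges: list[Edge] = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            r = float(values[i, j])
            if np.isfinite(r) and r * r >= r2_threshold:
                edges.append(Edge(names[i], names[j], r))
                graph.add_edge(names[i], names[j], r=r)
    components = [sorted(c) for c in nx.connected_components(graph)
                  if len(c) >= 2]
    components.sort(key=lambda c: (-len(c), c))
    return RelevanceNetwork(
        nodes=names,
        edges=sorted(edges, key=lambda e: (e.node_a, e.node_b)),
        components=components,
        r2_threshold=r2_threshold,
    )


# ---------------------------------------------------------------------------

def annotate_components(network: RelevanceNetwork,
                        mature_contexts=None,
                        conservation_calls=None) -> pd.DataFrame:
    """Per-component report: size, conservation mix, clustered members.

    ``mature_contexts`` is the list from
    :func:`adipomir.genomic_context.mature_context`; ``conservation_calls``
    the list from :func:`adipomir.conservation_seeds.classify_all`.  Nodes
    without attributes are tallied as "unknown".
    """
    ctx_by_name = {m.name: m for m in (mature_contexts or [])}
    cons_by_name = {c.mature_id: c for c in (conservation_calls or [])}

    rows = []
    for rank, comp in enumerate(network.components, start=1):
        cons_counts: dict[str, int] = {}
        clustered = 0
        cluster_ids: set[str] = set()
        for node in comp:
            call = cons_by_name.get(node)
            cls = call.conservation_class if call else "unknown"
            cons_counts[cls] = cons_counts.get(cls, 0) + 1
            ctx = ctx_by_name.get(node)
            if ctx is None:
                continue
            if ctx.clustered:
                clustered += 1
            cluster_ids.update(cid for _, _, cid in ctx.loci if cid)
        size = len(comp)
        row = {
            "component": rank,
            "size": size,
            "members": ",".join(comp),
            "n_clustered": clustered,
            "cluster_ids": ",".join(sorted(cluster_ids)) or "-",
        }
        for cls in ("highly_conserved", "conserved", "poorly_conserved",
                    "unknown"):
            k = cons_counts.get(cls, 0)
            row[f"n_{cls}"] = k
            row[f"pct_{cls}"] = 100.0 * k / size
        rows.append(row)
    return pd.DataFrame(rows)
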