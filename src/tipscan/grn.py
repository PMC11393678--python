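"""Gene regulatory networks from per-window interaction matrices.

The fitted cross-species interaction matrix ``A`` of a window is read as a
directed, signed GRN (edge ``j -> i`` for ``A_ij != 0``).  Edges are
rescaled by the expression of the sender (regulator) gene, so regulators
that are not expressed in a window contribute no active edges, and weak
edges below a quantile threshold are dropped.  Community structure
(Girvan-Newman or Clauset-Newman-Moore greedy modularity) and betweenness
centrality then summarize how the network rearranges along the lineage:
attractor windows show modular, compartmentalized networks, tipping windows
denser and less modular ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .model import SplicingModelFit
from .windows import LineageStabilityProfile, SplicingCounts

__all__ = [
    "build_grn",
    "detect_communities",
    "betweenness_ranking",
    "edge_weight_distribution",
    "community_trajectory",
    "EdgeWeightSummary",
]

COMMUNITY_ALGORITHMS = ("girvan_newman", "greedy_modularity")


def build_grn(
    fit: SplicingModelFit,
    mean_expression: np.ndarray,
    edge_threshold: float = 0.75,
) -> nx.DiGraph:
    """Directed, signed GRN of one window, rescaled by sender expression.

    ``mean_expression`` is the per-gene mean spliced expression in the
    window; it is min-max scaled across genes, and the edge ``j -> i``
    receives weight ``A_ij * scaled_expression_j``.  Zero-weight edges
    (including every outgoing edge of an unexpressed regulator) are
    removed, and so are edges whose |weight| falls below the
    ``edge_threshold`` quantile of the remaining nonzero |weights|.

    Edge attributes: ``weight`` (signed), ``abs_weight``, ``sign``
    ("activation"/"inhibition") and ``distance`` (1/|weight|, for
    shortest-path computations).  All genes appear as nodes even when
    isolated.
    """
    expr = np.asarray(mean_expression, dtype=float)
    m = fit.n_genes
    if expr.shape != (m,):
        raise ValueError("mean_expression must have one value per gene")
    if not 0 <= edge_threshold <= 1:
        raise ValueError("edge_threshold must be a quantile in [0, 1]")
    lo, hi = expr.min(), expr.max()
    scaled = (expr - lo) / (hi - lo) if hi > lo else np.zeros(m)

    a = fit.interaction_matrix
    weights = a * scaled[None, :]  # column j scaled by sender j
    nz = np.abs(weights[weights != 0])
    cutoff = np.quantile(nz, edge_threshold) if nz.size else np.inf

    graph = nx.DiGraph()
    graph.add_nodes_from(fit.gene_names)
    for i in range(m):
        for j in range(m):
            w = weights[i, j]
            if i == j or w == 0 or abs(w) < cutoff:
                continue
            graph.add_edge(
                fit.gene_names[j],
                fit.gene_names[i],
                weight=float(w),
                abs_weight=float(abs(w)),
                sign="activation" if w > 0 else "inhibition",
                distance=1.0 / abs(w),
            )
    return graph


def _undirected_projection(graph: nx.Graph | nx.DiGraph) -> nx.Graph:
    """Undirected view with |weight| edges (antiparallel pairs summed)."""
    und = nx.Graph()
    und.add_nodes_from(graph.nodes)
    for u, v, data in graph.edges(data=True):
        w = abs(data.get("weight", 1.0))
        if und.has_edge(u, v):
            und[u][v]["weight"] += w
        else:
            und.add_edge(u, v, weight=w)
    for u, v, data in und.edges(data=True):
        data["distance"] = 1.0 / data["weight"] if data["weight"] > 0 else np.inf
    return und


def _best_modularity_partition(
    und: nx.Graph, candidates: list[list[set]]
) -> tuple[list[set], float]:
    best, best_q = None, -np.inf
    for part in candidates:
        q = nx.community.modularity(und, part, weight="weight")
        if q > best_q:
            best, best_q = part, q
    return best, best_q


def detect_communities(
    graph: nx.Graph | nx.DiGraph,
    algorithm: str = "greedy_modularity",
) -> tuple[list[set], int]:
    """Community partition and count of a (window) GRN.

    The graph is projected to an undirected |weight| graph (the modularity
    algorithms are undirected).  ``greedy_modularity`` runs
    Clauset-Newman-Moore greedy maximization; ``girvan_newman`` evaluates
    the divisive hierarchy (seeded with the connected-component partition)
    and keeps the level of maximal weighted modularity, removing at each
    step the edge of highest distance-weighted betweenness.  Isolated nodes
    count as singleton communities; an empty graph has count 0.
    """
    if algorithm not in COMMUNITY_ALGORITHMS:
        raise ValueError(f"algorithm must be one of {COMMUNITY_ALGORITHMS}")
    und = _undirected_projection(graph)
    if und.number_of_nodes() == 0:
        return [], 0
    if und.number_of_edges() == 0:
        partition = [{n} for n in und.nodes]
        return partition, len(partition)

    if algorithm == "greedy_modularity":
        partition = [set(c) for c in nx.community.greedy_modularity_communities(und, weight="weight")]
    else:
        components = [set(c) for c in nx.connected_components(und)]
        candidates = [components]

        def heaviest_traffic_edge(g: nx.Graph):
            ebc = nx.edge_betweenness_centrality(g, weight="distance")
            return max(ebc, key=ebc.get)

        for level in nx.community.girvan_newman(und, most_valuable_edge=heaviest_traffic_edge):
            candidates.append([set(c) for c in level])
        partition, _ = _best_modularity_partition(und, candidates)
    return partition, len(partition)


def betweenness_ranking(graph: nx.Graph | nx.DiGraph, k: int) -> list[str]:
    """Top ``k`` genes by betweenness centrality; ties broken alphabetically.

    Shortest paths use the edge ``distance`` attribute (1/|weight|) when
    present, and hop counts otherwise.
    """
    if k > graph.number_of_nodes():
        raise ValueError("k exceeds the number of nodes")
    has_distance = all("distance" in d for _, _, d in graph.edges(data=True))
    weight = "distance" if (graph.number_of_edges() and has_distance) else None
    centrality = nx.betweenness_centrality(graph, weight=weight, normalized=True)
    ranked = sorted(centrality, key=lambda node: (-centrality[node], node))
    return ranked[:k]


@dataclass
class EdgeWeightSummary:
    """Absolute edge weights of one GRN with simple spread statistics."""

    values: np.ndarray
    iqr: float
    median: float
    n_above: int
    threshold: float

    @property
    def n_edges(self) -> int:
        return self.values.size


def edge_weight_distribution(
    graph: nx.Graph | nx.DiGraph, threshold: float = 0.0
) -> EdgeWeightSummary:
    """All |edge weights| plus interquartile range and count above threshold.

    The IQR is the 75th minus the 25th percentile with linear interpolation
    (numpy's default quantile rule).  An empty graph yields an empty summary.
    """
    values = np.sort(
        np.array([abs(d.get("weight", 1.0)) for _, _, d in graph.edges(data=True)], dtype=float)
    )
    if values.size == 0:
        return EdgeWeightSummary(values=values, iqr=0.0, median=np.nan, n_above=0, threshold=threshold)
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return EdgeWeightSummary(
        values=values,
        iqr=float(q3 - q1),
        median=float(med),
        n_above=int(np.count_nonzero(values > threshold)),
        threshold=threshold,
    )


def community_trajectory(
    profile: LineageStabilityProfile,
    counts: SplicingCounts | None = None,
    algorithms: tuple[str, ...] = COMMUNITY_ALGORITHMS,
    edge_threshold: float = 0.75,
) -> pd.DataFrame:
    """Community counts (and edge-weight spread) per window along the lineage.

    Builds the sender-rescaled GRN of every fitted window from the profile's
    stored full-window fits and mean expressions, then applies each
    community algorithm.  Returns a tidy frame with one row per window and
    columns ``n_communities_<algorithm>``, ``n_edges`` and ``weight_iqr``.
    ``counts`` is accepted for interface symmetry but the profile already
    carries everything needed.
    """
    del counts  # profile stores per-window mean expression
    rows = []
    for w, fit in enumerate(profile.fits):
        row: dict = {"window": w, "position": profile.window_positions[w]}
        if fit is None:
            rows.append(row)
            continue
        usable = fit.drop_missing()
        keep = [profile.gene_names.index(g) for g in usable.gene_names]
        graph = build_grn(usable, profile.mean_expression[w][keep], edge_threshold)
        summary = edge_weight_distribution(graph)
        row["n_edges"] = graph.number_of_edges()
        row["weight_iqr"] = summary.iqr
        for algorithm in algorithms:
            _, count = detect_communities(graph, algorithm)
            row[f"n_communities_{algorithm}"] = count
        rows.append(row)
    return pd.DataFrame(rows).set_index("window")
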