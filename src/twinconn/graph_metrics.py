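"""Graph-theoretical features of binarized and weighted FC matrices.

Six node-level features per ROI (degree, strength of positive weights,
strength of negative weights, clustering coefficient, local efficiency,
betweenness centrality) and five whole-network features (global efficiency,
characteristic path length, mean degree, density, Louvain modularity), plus
the assembly of the subject-by-feature table that the twin analysis consumes.

Conventions (binary, undirected graphs throughout):

* betweenness is left unnormalized — raw counts of unordered source-target
  pairs whose shortest paths pass through the node;
* local efficiency of a node is the global efficiency of the subgraph
  induced by its neighbours (0 when it has fewer than 2 neighbours);
* characteristic path length averages finite distances only; a flag records
  whether disconnected pairs were excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io_model import (
    BinaryFCMatrix,
    ParcellationLabels,
    ValidationError,
    WeightedFCMatrix,
)

__all__ = [
    "NodeMetrics",
    "NetworkMetrics",
    "NODE_METRIC_NAMES",
    "NETWORK_METRIC_NAMES",
    "node_metrics_binary",
    "node_strengths_signed",
    "network_metrics",
    "louvain_modularity",
    "modularity_from_partition",
    "feature_columns",
    "extract_feature_table",
]

NODE_METRIC_NAMES = (
    "degree",
    "strength_pos",
    "strength_neg",
    "clustering",
    "local_efficiency",
    "betweenness",
)

NETWORK_METRIC_NAMES = (
    "global_efficiency",
    "char_path_length",
    "mean_degree",
    "density",
    "louvain_Q",
)


@dataclass(frozen=True)
class NodeMetrics:
    """Per-ROI graph features, each an array aligned with the parcellation."""

    degree: np.ndarray
    strength_pos: np.ndarray
    strength_neg: np.ndarray
    clustering: np.ndarray
    local_efficiency: np.ndarray
    betweenness: np.ndarray


@dataclass(frozen=True)
class NetworkMetrics:
    global_efficiency: float
    char_path_length: float
    mean_degree: float
    density: float
    disconnected: bool  # True if any node pair had no connecting path


def _graph_from_binary(matrix: BinaryFCMatrix) -> nx.Graph:
    g = nx.from_numpy_array(matrix.values)
    # from_numpy_array stores weight=1.0 attributes; drop them, graph is binary
    for _, _, d in g.edges(data=True):
        d.clear()
    return g


def node_metrics_binary(
    matrix: BinaryFCMatrix,
) -> dict[str, np.ndarray]:
    """Degree, clustering, local efficiency and betweenness per node.

    clustering(i) = 2 t_i / (k_i (k_i - 1)) with t_i the number of edges
    among i's neighbours; local_efficiency(i) is the global efficiency of the
    neighbour-induced subgraph; betweenness(i) sums sigma_st(i) / sigma_st
    over unordered pairs s != t != i (unnormalized).  Nodes with fewer than
    two neighbours get clustering = local_efficiency = 0.
    """
    g = _graph_from_binary(matrix)
    n = len(matrix.parcellation)
    degree = matrix.values.sum(axis=0)
    clustering = np.array([nx.clustering(g, i) for i in range(n)], dtype=float)
    betweenness_map = nx.betweenness_centrality(g, normalized=False)
    betweenness = np.array([betweenness_map[i] for i in range(n)], dtype=float)
    local_eff = np.zeros(n)
    for i in range(n):
        nbrs = list(g.neighbors(i))
        if len(nbrs) >= 2:
            local_eff[i] = nx.global_efficiency(g.subgraph(nbrs))
    return {
        "degree": degree,
        "clustering": clustering,
        "local_efficiency": local_eff,
        "betweenness": betweenness,
    }


def node_strengths_signed(matrix: WeightedFCMatrix) -> dict[str, np.ndarray]:
    """Sum of positive weights and of absolute negative weights per node."""
    w = matrix.values
    return {
        "strength_pos": np.where(w > 0, w, 0.0).sum(axis=1),
        "strength_neg": np.where(w < 0, -w, 0.0).sum(axis=1),
    }


def network_metrics(matrix: BinaryFCMatrix) -> NetworkMetrics:
    """Whole-network efficiency, path length, mean degree and density.

    Global efficiency averages 1/d(i, j) over all unordered pairs with
    1/inf = 0.  Characteristic path length averages the *finite* distances
    only; if any pair is disconnected the ``disconnected`` flag is set (and
    the value is NaN when no pair is connected at all).
    """
    n = len(matrix.parcellation)
    if n < 2:
        raise ValidationError("network metrics need at least 2 nodes")
    g = _graph_from_binary(matrix)
    n_pairs = n * (n - 1) // 2
    inv_sum = 0.0
    finite = []
    for src, dists in nx.all_pairs_shortest_path_length(g):
        for dst, d in dists.items():
            if dst > src:
                inv_sum += 1.0 / d
                finite.append(d)
    m = matrix.n_edges
    return NetworkMetrics(
        global_efficiency=inv_sum / n_pairs,
        char_path_length=float(np.mean(finite)) if finite else float("nan"),
        mean_degree=2.0 * m / n,
        density=m / n_pairs,
        disconnected=len(finite) < n_pairs,
    )


def modularity_from_partition(
    adjacency: np.ndarray, partition: Sequence[set[int]], gamma: float = 1.0
) -> float:
    """Newman modularity Q of a node partition of a binary graph.

    Q = sum_c [ e_c / m  -  gamma * (d_c / 2m)^2 ]  with e_c the number of
    within-community edges, d_c the total degree of community c, and m the
    edge count.
    """
    a = np.asarray(adjacency, dtype=float)
    m = np.triu(a, k=1).sum()
    if m == 0:
        raise ValidationError("modularity is undefined for an edgeless graph")
    q = 0.0
    for community in partition:
        idx = np.fromiter(community, dtype=int)
        e_c = np.triu(a[np.ix_(idx, idx)], k=1).sum()
        d_c = a[idx, :].sum()
        q += e_c / m - gamma * (d_c / (2.0 * m)) ** 2
    return float(q)


def louvain_modularity(
    matrix: BinaryFCMatrix,
    gamma: float = 1.0,
    seed: int = 0,
    n_restarts: int = 10,
) -> tuple[list[set[int]], float]:
    """Louvain community detection with seeded restarts.

    The heuristic is run ``n_restarts`` times with distinct seeded node
    orders and the partition with the highest Q is kept.  Q is always
    recomputed from the returned partition with
    :func:`modularity_from_partition`, so the reported value is
    self-consistent by construction.
    """
    g = _graph_from_binary(matrix)
    if g.number_of_edges() == 0:
        raise ValidationError("Louvain modularity requires at least one edge")
    best_q = -np.inf
    best: list[set[int]] = []
    for restart in range(n_restarts):
        communities = nx.community.louvain_communities(
            g, resolution=gamma, seed=seed + restart
        )
        q = modularity_from_partition(matrix.values, communities, gamma=gamma)
        if q > best_q:
            best_q = q
            best = [set(c) for c in communities]
    return best, best_q


# ---------------------------------------------------------------------------
# Feature-table assembly
# ---------------------------------------------------------------------------


def feature_columns(parcellation: ParcellationLabels) -> list[str]:
    """Deterministic feature-column order: links, node metrics, network metrics.

    For N ROIs this yields C(N, 2) link features ("link:A|B" with A before B
    in parcellation order), 6 N node features ("node:metric:ROI"), and 5
    network features ("net:name") — 4550 columns for the default N = 90.
    """
    labels = parcellation.labels
    cols = [
        f"link:{labels[i]}|{labels[j]}"
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    ]
    for metric in NODE_METRIC_NAMES:
        cols.extend(f"node:{metric}:{lab}" for lab in labels)
    cols.extend(f"net:{name}" for name in NETWORK_METRIC_NAMES)
    return cols


def extract_feature_table(
    cohort: Mapping[str, tuple[WeightedFCMatrix, BinaryFCMatrix]],
    seed: int = 0,
) -> pd.DataFrame:
    """Assemble the subject x feature table for a cohort of FC matrix pairs.

    Link weights come from the masked weighted matrix (upper triangle); the
    six node metrics and five network metrics follow.  All subjects must
    share one parcellation.  Louvain Q for a subject with an edgeless graph
    is stored as NaN (modularity is undefined there).
    """
    if not cohort:
        raise ValidationError("empty cohort")
    first = next(iter(cohort.values()))[0].parcellation
    for w, b in cohort.values():
        if w.parcellation.labels != first.labels or b.parcellation.labels != first.labels:
            raise ValidationError("subjects use different parcellations")
    iu = np.triu_indices(len(first), k=1)
    rows = {}
    for pos, (subject_id, (weighted, binary)) in enumerate(cohort.items()):
        node = node_metrics_binary(binary)
        node.update(node_strengths_signed(weighted))
        net = network_metrics(binary)
        try:
            _, q = louvain_modularity(binary, seed=seed + pos)
        except ValidationError:
            q = float("nan")
        row = np.concatenate(
            [weighted.values[iu]]
            + [node[metric] for metric in NODE_METRIC_NAMES]
            + [
                np.array(
                    [
                        net.global_efficiency,
                        net.char_path_length,
                        net.mean_degree,
                        net.density,
                        q,
                    ]
                )
            ]
        )
        rows[subject_id] = row
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=feature_columns(first)
    )
    table.index.name = "subject_id"
    return table


def feature_scale(feature_id: str) -> str:
    """Spatial scale of a feature id: "link", "node" or "network"."""
    prefix = feature_id.split(":", 1)[0]
    return {"link": "link", "node": "node", "net": "network"}[prefix]
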