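"""Biogeographic clustering of association projections and graph topology.

Each positively associated pair contributes one row to a stacked binary
matrix (associations x grid cells): 1 where its cADM predicts co-presence.
k-means on these rows groups associations sharing a biogeographic signature;
the number of clusters is chosen by mean silhouette over a scanned range.
Per-cluster association graphs (nodes = taxa, edges = associations weighted
by projected rho*) are then summarised by edge-level topology: normalized
edge betweenness centrality and the edges-per-node ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .projection import ProjectionResult

__all__ = [
    "ClusterResult",
    "stack_copresence",
    "cluster_signatures",
    "build_graph",
    "edge_betweenness",
    "edge_density",
    "conventional_density",
    "normalize_metrics_across_clusters",
]


@dataclass
class ClusterResult:
    """k-means partition of association signatures with silhouette scan."""

    association_ids: list
    labels: np.ndarray
    chosen_k: int
    silhouette_by_k: dict[int, float] = field(default_factory=dict)
    seed: int = 0

    def members(self, label: int) -> list:
        return [a for a, l in zip(self.association_ids, self.labels) if l == label]


def stack_copresence(projections: list[ProjectionResult]) -> np.ndarray:
    """Binary matrix (associations x valid cells): 1 = predicted co-presence.

    All projections must come from the same masked grid (identical valid
    cell indices).
    """
    if not projections:
        raise ValueError("no projections given")
    ref = projections[0].cell_indices
    rows = []
    for p in projections:
        if p.states is None:
            raise ValueError(f"projection for pair {p.pair} is not a cADM projection")
        if p.cell_indices.shape != ref.shape or not np.array_equal(p.cell_indices, ref):
            raise ValueError(
                f"projection for pair {p.pair} uses a different grid/mask"
            )
        rows.append((p.states == "copresence").astype(float))
    return np.vstack(rows)


def cluster_signatures(
    stacked: np.ndarray,
    k_range=range(2, 16),
    seed: int = 0,
    n_init: int = 10,
    max_silhouette_rows: int = 5000,
) -> ClusterResult:
    """k-means over a range of k; keep the k maximising mean silhouette.

    Euclidean distance on the raw 0/1 matrix; 10 restarts per k; the
    silhouette is computed on at most ``max_silhouette_rows`` seeded-sampled
    rows for tractability. Deterministic for a fixed seed.
    """
    stacked = np.asarray(stacked, dtype=float)
    k_range = list(k_range)
    n = stacked.shape[0]
    if n < max(k_range) + 1:
        raise ValueError(
            f"need at least max(k_range)+1 = {max(k_range) + 1} associations, got {n}"
        )
    rng = np.random.default_rng(seed)
    if n > max_silhouette_rows:
        sil_rows = np.sort(rng.choice(n, size=max_silhouette_rows, replace=False))
    else:
        sil_rows = np.arange(n)
    n_distinct = np.unique(stacked, axis=0).shape[0]
    silhouettes: dict[int, float] = {}
    fits: dict[int, np.ndarray] = {}
    for k in k_range:
        if k > n_distinct:
            continue  # k-means cannot place more clusters than distinct rows
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels = km.fit_predict(stacked)
        if np.unique(labels[sil_rows]).size < 2:
            continue  # silhouette undefined for a single effective cluster
        silhouettes[k] = float(silhouette_score(stacked[sil_rows], labels[sil_rows]))
        fits[k] = labels
    if not silhouettes:
        raise ValueError(
            "silhouette undefined for every k (e.g. all rows identical); "
            "cannot select a clustering"
        )
    chosen_k = max(silhouettes, key=lambda k: (silhouettes[k], -k))
    return ClusterResult(
        association_ids=list(range(n)),
        labels=fits[chosen_k],
        chosen_k=chosen_k,
        silhouette_by_k=silhouettes,
        seed=seed,
    )


def build_graph(associations, cluster_label=None) -> nx.Graph:
    """Undirected taxon graph from (pair, rho*) records.

    ``associations`` iterates over ``((taxon_j, taxon_k), weight)``.
    Duplicate pairs (in either orientation) and self-loops are rejected.
    """
    g = nx.Graph(cluster=cluster_label)
    for (tj, tk), w in associations:
        if tj == tk:
            raise ValueError(f"self-loop on taxon {tj!r}")
        if g.has_edge(tj, tk):
            raise ValueError(f"duplicate pair ({tj!r}, {tk!r})")
        if not np.isfinite(w):
            raise ValueError(f"non-finite weight for pair ({tj!r}, {tk!r})")
        g.add_edge(tj, tk, weight=float(w))
    return g


def edge_betweenness(graph: nx.Graph) -> dict:
    """Normalized edge betweenness centrality on unweighted shortest paths."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    return nx.edge_betweenness_centrality(graph, normalized=True, weight=None)


def edge_density(graph: nx.Graph) -> float:
    """Edges-per-node ratio E/N (the field's edge-level density measure)."""
    n = graph.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    return graph.number_of_edges() / n


def conventional_density(graph: nx.Graph) -> float:
    """Standard graph density 2E/(N(N-1)), for comparison with E/N."""
    return nx.density(graph)


def normalize_metrics_across_clusters(values: dict) -> tuple[dict, float]:
    """Min-max normalise a per-cluster metric to [0, 1].

    Returns (normalised map, spread) where spread = (max - min)/max * 100,
    the relative range of the raw values in percent. All-equal values map to
    0 with spread 0.
    """
    if len(values) < 2:
        raise ValueError("need at least two clusters")
    vals = np.array([values[k] for k in values], dtype=float)
    vmin, vmax = vals.min(), vals.max()
    if vmax == vmin:
        return {k: 0.0 for k in values}, 0.0
    normed = {k: float((values[k] - vmin) / (vmax - vmin)) for k in values}
    spread = float((vmax - vmin) / vmax * 100.0)
    return normed, spread
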