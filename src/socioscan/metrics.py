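"""Weighted social networks and their global, nodal and clustering metrics.

Edge weights are HWI values (similarities in (0, 1]); zero-HWI dyads are
absent edges.  Geodesic-based metrics (betweenness, closeness) run on
distances d = 1/weight, the usual conversion for association-index networks.
Eigenvector centrality is the dominant eigenvector of the weight matrix,
normalised so the most central individual scores 1.  Community structure is
found with the walktrap algorithm (short random walks, 4 steps), cutting the
dendrogram at maximum weighted modularity Q.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd

from .association import AssociationMatrix

NODE_METRICS = ("weighted_degree", "betweenness", "closeness", "eigenvector")


@dataclass
class SocialNetwork:
    """A weighted (di)graph of association indices for one stratum."""

    graph: nx.Graph | nx.DiGraph
    context: str
    data_type: str

    @property
    def directed(self) -> bool:
        return self.graph.is_directed()

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def tag(self) -> str:
        return f"{self.context}_{self.data_type}"

    def weight_matrix(self) -> np.ndarray:
        return nx.to_numpy_array(self.graph, nodelist=self.nodes, weight="weight")

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, path)

    def write_edgelist(self, path: str | Path) -> None:
        rows = [(u, v, d["weight"]) for u, v, d in self.graph.edges(data=True)]
        pd.DataFrame(rows, columns=["from", "to", "weight"]).to_csv(path, index=False)


@dataclass
class MetricTable:
    """Per-node centralities plus global density and clustering for one network."""

    tag: str
    density: float
    table: pd.DataFrame  # index = individual id, columns = NODE_METRICS
    membership: dict[str, int] = field(default_factory=dict)
    modularity: float = float("nan")

    def metric(self, name: str) -> pd.Series:
        return self.table[name]

    def to_tidy(self) -> pd.DataFrame:
        tidy = self.table.reset_index(names="id").melt(id_vars="id", var_name="metric", value_name="value")
        tidy.insert(0, "network", self.tag)
        return tidy

    def write_csv(self, path: str | Path) -> None:
        self.to_tidy().to_csv(path, index=False)


def build_network(matrix: AssociationMatrix) -> SocialNetwork:
    """One edge per nonzero HWI entry; directedness follows the data type."""
    g: nx.Graph | nx.DiGraph = nx.DiGraph() if matrix.directed else nx.Graph()
    g.add_nodes_from(matrix.ids)
    n = len(matrix.ids)
    for i in range(n):
        cols = range(n) if matrix.directed else range(i + 1, n)
        for j in cols:
            w = matrix.hwi[i, j]
            if i != j and w > 0:
                g.add_edge(matrix.ids[i], matrix.ids[j], weight=float(w))
    return SocialNetwork(graph=g, context=matrix.context, data_type=matrix.data_type)


def density(net: SocialNetwork) -> float:
    """Proportion of possible edges present (weights ignored)."""
    n = net.graph.number_of_nodes()
    if n < 2:
        raise ValueError("density undefined for networks with fewer than 2 nodes")
    m = net.graph.number_of_edges()
    possible = n * (n - 1) if net.directed else n * (n - 1) / 2
    return m / possible


def eigenvector_centrality(
    W: np.ndarray, tol: float = 1e-10, max_iter: int = 10_000
) -> np.ndarray:
    """Dominant right eigenvector of W by power iteration, max-normalised.

    Deterministic uniform start; falls back to the symmetrised matrix when
    the iteration fails to converge (degenerate spectral gap).  Zero matrix
    returns zeros.
    """
    n = W.shape[0]
    if n == 0 or not W.any():
        return np.zeros(n)
    x = np.full(n, 1.0 / np.sqrt(n))
    # positive diagonal shift breaks the ±λ tie on bipartite graphs without
    # changing the dominant eigenvector
    shift = float(np.abs(W).max())
    for _ in range(max_iter):
        y = W @ x + shift * x
        norm = np.linalg.norm(y)
        if norm == 0:
            break
        y /= norm
        if np.linalg.norm(y - x) < tol:
            x = y
            break
        x = y
    else:
        Ws = (W + W.T) / 2.0
        if not np.array_equal(Ws, W):
            return eigenvector_centrality(Ws, tol=tol, max_iter=max_iter)
        warnings.warn("eigenvector power iteration did not converge")
    x = np.abs(x)
    m = x.max()
    return x / m if m > 0 else x


def node_metrics(net: SocialNetwork, weighted: bool = True) -> MetricTable:
    """Weighted degree, betweenness, closeness and eigenvector centrality.

    * weighted degree — sum of incident edge weights (in + out if directed);
    * betweenness — standard shortest-path-count betweenness (unnormalised)
      on geodesic distances d = 1/weight;
    * closeness — 1 / Σ geodesic distances to reachable others (0 for an
      isolate);
    * eigenvector — dominant eigenvector of the weight matrix, max = 1.

    ``weighted=False`` binarises the graph for the geodesic metrics.
    """
    g = net.graph
    nodes = net.nodes
    if g.number_of_edges() == 0:
        warnings.warn(f"network {net.tag}: no edges; all metrics zero")
        zeros = pd.DataFrame(0.0, index=nodes, columns=list(NODE_METRICS))
        return MetricTable(tag=net.tag, density=0.0 if len(nodes) >= 2 else float("nan"), table=zeros)

    h = g.copy()
    for u, v, d in h.edges(data=True):
        d["distance"] = 1.0 / d["weight"] if weighted else 1.0

    if net.directed:
        wdeg = {
            v: g.in_degree(v, weight="weight") + g.out_degree(v, weight="weight") for v in nodes
        }
    else:
        wdeg = dict(g.degree(weight="weight"))

    btw = nx.betweenness_centrality(h, weight="distance", normalized=False)

    clo = {}
    for v in nodes:
        dists = nx.single_source_dijkstra_path_length(h, v, weight="distance")
        total = sum(d for u, d in dists.items() if u != v)
        clo[v] = 1.0 / total if total > 0 else 0.0

    W = net.weight_matrix()
    eig = eigenvector_centrality(W if net.directed else W)
    table = pd.DataFrame(
        {
            "weighted_degree": [float(wdeg[v]) for v in nodes],
            "betweenness": [float(btw[v]) for v in nodes],
            "closeness": [float(clo[v]) for v in nodes],
            "eigenvector": eig,
        },
        index=pd.Index(nodes, name="id"),
    )
    membership, q = walktrap_clusters(net)
    return MetricTable(tag=net.tag, density=density(net), table=table, membership=membership, modularity=q)


def _to_igraph_undirected(net: SocialNetwork) -> tuple[ig.Graph, list[str]]:
    nodes = net.nodes
    index = {v: k for k, v in enumerate(nodes)}
    weights: dict[tuple[int, int], float] = {}
    for u, v, d in net.graph.edges(data=True):
        key = (min(index[u], index[v]), max(index[u], index[v]))
        # directed graphs collapse to undirected by summing reciprocal weights
        weights[key] = weights.get(key, 0.0) + d["weight"]
    g = ig.Graph(n=len(nodes), edges=list(weights.keys()))
    g.es["weight"] = list(weights.values())
    return g, nodes


def walktrap_clusters(net: SocialNetwork, steps: int = 4) -> tuple[dict[str, int], float]:
    """Walktrap community detection, cut at maximum weighted modularity Q.

    Returns a membership map (labels 0, 1, ... ordered by each cluster's
    smallest member id) and the modularity of the chosen partition.  An
    edgeless network yields singleton clusters with Q = 0.
    """
    g, nodes = _to_igraph_undirected(net)
    if g.ecount() == 0:
        return {v: k for k, v in enumerate(nodes)}, 0.0
    dendro = g.community_walktrap(weights="weight", steps=steps)
    clustering = dendro.as_clustering()  # cut maximising modularity
    raw = clustering.membership
    q = g.modularity(raw, weights="weight")
    # deterministic relabeling: clusters ordered by smallest member id
    by_cluster: dict[int, str] = {}
    for v, c in zip(nodes, raw):
        if c not in by_cluster or v < by_cluster[c]:
            by_cluster[c] = v
    order = {c: rank for rank, (c, _) in enumerate(sorted(by_cluster.items(), key=lambda kv: kv[1]))}
    return {v: order[c] for v, c in zip(nodes, raw)}, float(q)


def modularity_of_partition(net: SocialNetwork, membership: dict[str, int]) -> float:
    """Weighted Newman modularity of an arbitrary partition (shared helper)."""
    g, nodes = _to_igraph_undirected(net)
    if g.ecount() == 0:
        return 0.0
    return float(g.modularity([membership[v] for v in nodes], weights="weight"))
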