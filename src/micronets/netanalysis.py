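"""Local and global properties of one network.

Shortest-path based measures (betweenness, closeness, average path
length) run on dissimilarity edge weights; connection-strength based
measures (degree, eigenvector centrality, modularity, the Barrat
clustering coefficient) run on similarity weights.  Normalizations
follow the conventions deg* = deg/(n-1), betw* = 2 betw/(n^2-3n+2),
close* = close/(n-1) and eig* = eig/max(eig).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial.distance import squareform

from .containers import AdjacencyBundle

__all__ = [
    "NodeCentralities",
    "ClusterAssignment",
    "GlobalMetrics",
    "NetworkProperties",
    "centralities",
    "detect_hubs",
    "cluster_nodes",
    "global_metrics",
    "analyze_network",
]

GLOBAL_METRIC_NAMES = ("avg_path_length", "clustering_coefficient",
                       "modularity", "vertex_connectivity",
                       "edge_connectivity", "density")


@dataclass
class NodeCentralities:
    node_ids: list[str]
    degree: np.ndarray
    betweenness: np.ndarray
    closeness: np.ndarray
    eigenvector: np.ndarray
    degree_norm: np.ndarray
    betweenness_norm: np.ndarray
    closeness_norm: np.ndarray
    eigenvector_norm: np.ndarray
    weighted: bool
    notes: dict = field(default_factory=dict)

    def normalized(self, measure: str) -> np.ndarray:
        return getattr(self, f"{measure}_norm")


@dataclass
class ClusterAssignment:
    node_ids: list[str]
    labels: np.ndarray  # 0 = isolated / unclustered
    method: str
    params: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return int(len(set(self.labels[self.labels > 0])))


@dataclass
class GlobalMetrics:
    avg_path_length: float
    clustering_coefficient: float
    modularity: float
    vertex_connectivity: int
    edge_connectivity: int
    density: float
    notes: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in GLOBAL_METRIC_NAMES}


@dataclass
class NetworkProperties:
    centralities: NodeCentralities
    hubs: list[str]
    clusters: ClusterAssignment
    global_metrics: GlobalMetrics

    def to_dict(self) -> dict:
        c = self.centralities
        return {
            "nodes": [
                {
                    "id": nid,
                    "degree": float(c.degree[i]),
                    "degree_norm": float(c.degree_norm[i]),
                    "betweenness": float(c.betweenness[i]),
                    "betweenness_norm": float(c.betweenness_norm[i]),
                    "closeness": float(c.closeness[i]),
                    "closeness_norm": float(c.closeness_norm[i]),
                    "eigenvector": float(c.eigenvector[i]),
                    "eigenvector_norm": float(c.eigenvector_norm[i]),
                    "cluster": int(self.clusters.labels[i]),
                    "hub": nid in self.hubs,
                }
                for i, nid in enumerate(c.node_ids)
            ],
            "hubs": list(self.hubs),
            "global": {k: (float(v) if not isinstance(v, dict) else v)
                       for k, v in self.global_metrics.as_dict().items()},
            "notes": {**self.centralities.notes,
                      **self.global_metrics.notes},
        }


def _distance_matrix(bundle: AdjacencyBundle) -> np.ndarray:
    """All-pairs shortest-path lengths on dissimilarity weights."""
    p = bundle.n_nodes
    w = np.where(bundle.edge_indicator, bundle.dissimilarity, 0.0)
    graph = csr_matrix(w)
    return dijkstra(graph, directed=False, unweighted=False)


def _components(bundle: AdjacencyBundle) -> np.ndarray:
    graph = csr_matrix(bundle.edge_indicator.astype(np.int8))
    return connected_components(graph, directed=False)[1]


def _power_iteration_eigenvector(S: np.ndarray, tol: float = 1e-10,
                                 max_iter: int = 1000) -> np.ndarray:
    p = S.shape[0]
    # diagonal shift keeps the leading eigenvector but guarantees the
    # iteration converges even on bipartite graphs (lambda_min = -lambda_max)
    shift = max(1.0, float(S.max()))
    A = S + shift * np.eye(p)
    x = np.full(p, 1.0 / np.sqrt(p))
    for _ in range(max_iter):
        y = A @ x
        norm = np.linalg.norm(y)
        if norm == 0:
            return np.zeros(p)
        y /= norm
        if np.linalg.norm(y - x) < tol:
            x = y
            break
        x = y
    if x.sum() < 0:
        x = -x
    return np.abs(x)  # sign fixed positive


def _betweenness(bundle: AdjacencyBundle) -> np.ndarray:
    """Pair-counted betweenness (each unordered pair contributes once)."""
    import networkx as nx

    g = bundle.to_graph()
    bc = nx.betweenness_centrality(g, weight="dissimilarity",
                                   normalized=False)
    return np.array([bc[nid] for nid in bundle.node_ids])


def centralities(bundle: AdjacencyBundle,
                 weighted: Optional[bool] = None,
                 include_betweenness: bool = True) -> NodeCentralities:
    """Degree, betweenness, closeness and eigenvector centrality.

    Eigenvector centrality is computed by power iteration on the
    similarity matrix of the largest connected component (zero
    elsewhere).  Closeness on a disconnected graph sums distances
    within the node's component only.
    """
    p = bundle.n_nodes
    if p < 2:
        raise ValueError("centralities need at least 2 nodes")
    if weighted is None:
        weighted = bundle.weighted
    notes: dict = {}
    if not bundle.edge_indicator.any():
        warnings.warn("empty network: all centralities are 0", RuntimeWarning)
        z = np.zeros(p)
        return NodeCentralities(list(bundle.node_ids), z, z.copy(), z.copy(),
                                z.copy(), z.copy(), z.copy(), z.copy(),
                                z.copy(), weighted, {"empty": True})

    if weighted:
        degree = bundle.similarity.sum(axis=1)
    else:
        degree = bundle.edge_indicator.sum(axis=1).astype(float)
    degree_norm = degree / (p - 1)

    D = _distance_matrix(bundle)
    finite = np.isfinite(D)
    np.fill_diagonal(finite, False)
    sums = np.where(finite, D, 0.0).sum(axis=1)
    with np.errstate(divide="ignore"):
        closeness = np.where(sums > 0, 1.0 / sums, 0.0)
    closeness_norm = closeness / (p - 1)
    if weighted and np.any(closeness_norm > 1):
        notes["closeness_norm_exceeds_unit"] = True

    if include_betweenness:
        betw = _betweenness(bundle)
    else:
        betw = np.zeros(p)
    denom = p * p - 3 * p + 2
    betw_norm = 2.0 * betw / denom if denom > 0 else np.zeros(p)

    comp = _components(bundle)
    comp_sizes = np.bincount(comp)
    # largest component by node count, ties by lowest label
    largest = int(np.argmax(comp_sizes))
    mask = comp == largest
    eig = np.zeros(p)
    if mask.sum() >= 2:
        S = bundle.similarity[np.ix_(mask, mask)]
        eig[mask] = _power_iteration_eigenvector(S)
    emax = eig.max()
    eig_norm = eig / emax if emax > 0 else np.zeros(p)

    return NodeCentralities(list(bundle.node_ids), degree, betw, closeness,
                            eig, degree_norm, betw_norm, closeness_norm,
                            eig_norm, weighted, notes)


def detect_hubs(cent: NodeCentralities,
                measures: Sequence[str] = ("eigenvector",),
                method: str = "empirical_quantile",
                q: float = 0.95) -> list[str]:
    """Nodes above the q-quantile of a centrality distribution.

    ``lognormal_quantile`` fits a log-normal by maximum likelihood to
    the positive centrality values and thresholds at its q-quantile;
    ``empirical_quantile`` uses the sample quantile directly.  With
    several measures a node must exceed the threshold for all of them
    (the "most central in every respect" intersection rule).
    """
    if not (0 < q < 1):
        raise ValueError("q must lie in (0, 1)")
    if method not in ("empirical_quantile", "lognormal_quantile"):
        raise ValueError(f"unknown hub method {method!r}")
    hub_mask = np.ones(len(cent.node_ids), dtype=bool)
    for m in measures:
        vals = cent.normalized(m)
        if np.all(vals == vals[0]):
            warnings.warn(f"all {m} centralities equal; no hubs detected",
                          RuntimeWarning)
            return []
        if method == "empirical_quantile":
            thr = np.quantile(vals, q)
        else:
            pos = vals[vals > 0]
            if pos.size < 2:
                warnings.warn(f"too few positive {m} values for a "
                              "log-normal fit; no hubs", RuntimeWarning)
                return []
            mu = np.log(pos).mean()
            sigma = np.log(pos).std(ddof=0)
            if sigma == 0:
                warnings.warn(f"degenerate log-normal fit for {m}; no hubs",
                              RuntimeWarning)
                return []
            thr = stats.lognorm.ppf(q, s=sigma, scale=np.exp(mu))
        hub_mask &= vals > thr
    return [nid for nid, h in zip(cent.node_ids, hub_mask) if h]


def _relabel(labels: np.ndarray, isolated: np.ndarray) -> np.ndarray:
    """Contiguous positive labels for clustered nodes, 0 for isolated."""
    out = np.zeros(labels.shape, dtype=int)
    nxt = 1
    seen: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if isolated[i]:
            continue
        if lab not in seen:
            seen[lab] = nxt
            nxt += 1
        out[i] = seen[lab]
    return out


def cluster_nodes(bundle: AdjacencyBundle,
                  method: str = "greedy_modularity",
                  k: Optional[int] = None,
                  height: Optional[float] = None,
                  linkage: str = "average") -> ClusterAssignment:
    """Partition the network nodes into clusters (modules).

    greedy_modularity agglomerates communities maximizing
    similarity-weighted modularity; hierarchical clusters the
    dissimilarity matrix (non-edges at distance 1) and cuts the tree at
    ``k`` clusters or at ``height``; edge_betweenness removes the edge
    of highest (dissimilarity-weighted) betweenness repeatedly and
    returns the partition of maximum modularity along the removal
    sequence.  Isolated nodes are labeled 0.
    """
    import networkx as nx

    p = bundle.n_nodes
    isolated = ~bundle.edge_indicator.any(axis=1)
    ids = list(bundle.node_ids)

    if method == "greedy_modularity":
        g = bundle.to_graph()
        g.remove_nodes_from([ids[i] for i in np.nonzero(isolated)[0]])
        labels = np.zeros(p, dtype=int)
        if g.number_of_edges() > 0:
            comms = nx.community.greedy_modularity_communities(
                g, weight="similarity")
            for c_idx, comm in enumerate(comms, start=1):
                for nid in comm:
                    labels[ids.index(nid)] = c_idx
        return ClusterAssignment(ids, _relabel(labels, isolated), method)

    if method == "hierarchical":
        if linkage not in ("single", "complete", "average", "ward"):
            raise ValueError(f"unknown linkage {linkage!r}")
        if k is None and height is None:
            raise ValueError("hierarchical clustering needs a cut "
                             "parameter k or height")
        d = np.where(bundle.edge_indicator, bundle.dissimilarity, 1.0)
        np.fill_diagonal(d, 0.0)
        Z = scipy_linkage(squareform(d, checks=False), method=linkage)
        if k is not None:
            labels = fcluster(Z, t=int(k), criterion="maxclust")
        else:
            labels = fcluster(Z, t=float(height), criterion="distance")
        return ClusterAssignment(ids, _relabel(labels, isolated), method,
                                 {"linkage": linkage, "k": k,
                                  "height": height})

    if method == "edge_betweenness":
        g = bundle.to_graph()
        g.remove_nodes_from([ids[i] for i in np.nonzero(isolated)[0]])
        best_q, best_parts = -np.inf, [set(c) for c in
                                       nx.connected_components(g)]
        work = g.copy()
        while work.number_of_edges() > 0:
            parts = [set(c) for c in nx.connected_components(work)]
            q = nx.community.modularity(g, parts, weight="similarity") \
                if g.number_of_edges() else 0.0
            if q > best_q:
                best_q, best_parts = q, parts
            ebc = nx.edge_betweenness_centrality(work, weight="dissimilarity")
            work.remove_edge(*max(ebc, key=ebc.get))
        labels = np.zeros(p, dtype=int)
        for c_idx, comm in enumerate(best_parts, start=1):
            for nid in comm:
                labels[ids.index(nid)] = c_idx
        return ClusterAssignment(ids, _relabel(labels, isolated), method)

    raise ValueError(f"unknown clustering method {method!r}")


def _modularity(sim: np.ndarray, labels: np.ndarray) -> float:
    """Similarity-weighted Newman modularity of a label partition."""
    A = np.array(sim, dtype=float)
    np.fill_diagonal(A, 0.0)
    two_m = A.sum()
    if two_m == 0:
        return 0.0
    k = A.sum(axis=1)
    # isolated nodes (label 0) count as singleton communities
    labs = labels.copy()
    nxt = labs.max() + 1
    for i in np.nonzero(labs == 0)[0]:
        labs[i] = nxt
        nxt += 1
    q = 0.0
    for lab in np.unique(labs):
        m = labs == lab
        q += A[np.ix_(m, m)].sum() / two_m - (k[m].sum() / two_m) ** 2
    return float(q)


def _barrat_coefficient(bundle: AdjacencyBundle) -> float:
    """Barrat et al. weighted clustering coefficient, averaged over nodes
    of degree >= 2."""
    a = bundle.edge_indicator.astype(float)
    w = np.where(bundle.edge_indicator, bundle.similarity, 0.0)
    k = a.sum(axis=1)
    s = w.sum(axis=1)
    vals = []
    p = a.shape[0]
    for i in range(p):
        if k[i] < 2 or s[i] == 0:
            continue
        wi = w[i]
        ai = a[i]
        # sum over ordered pairs (j, h) of a_ij a_ih a_jh (w_ij + w_ih)/2
        total = 0.0
        nbrs = np.nonzero(ai)[0]
        for j in nbrs:
            # a_jh over h in nbrs
            ah = a[j, nbrs]
            total += np.sum(ah * (wi[j] + wi[nbrs]) / 2.0)
        vals.append(total / (s[i] * (k[i] - 1)))
    return float(np.mean(vals)) if vals else 0.0


def _transitivity(adj: np.ndarray) -> float:
    a = adj.astype(float)
    np.fill_diagonal(a, 0.0)
    a2 = a @ a
    triangles = np.trace(a2 @ a)  # 6 x number of triangles
    triples = a2.sum() - np.trace(a2)  # 2 x number of connected triples
    return float(triangles / triples) if triples > 0 else 0.0


def global_metrics(bundle: AdjacencyBundle,
                   clusters: Optional[ClusterAssignment] = None,
                   weighted: Optional[bool] = None) -> GlobalMetrics:
    """Average path length, clustering coefficient, modularity,
    connectivity and density of the network.

    Path lengths average shortest dissimilarity-weighted paths over
    connected node pairs.  Modularity evaluates the supplied partition
    with similarity weights.  Connectivity and density look only at
    edge presence/absence and are flagged as not meaningful on a fully
    connected network.
    """
    import networkx as nx

    p = bundle.n_nodes
    if weighted is None:
        weighted = bundle.weighted
    notes: dict = {}
    n_edges = bundle.n_edges
    density = 2.0 * n_edges / (p * (p - 1)) if p > 1 else 0.0
    if n_edges == p * (p - 1) // 2 and p > 1:
        notes["fully_connected"] = ("connectivity and density are not "
                                    "meaningful for a fully connected "
                                    "network")

    D = _distance_matrix(bundle)
    iu = np.triu_indices(p, 1)
    finite = np.isfinite(D[iu])
    avg_path = float(D[iu][finite].mean()) if finite.any() else 0.0

    if weighted:
        cc = _barrat_coefficient(bundle)
    else:
        cc = _transitivity(bundle.edge_indicator)

    labels = clusters.labels if clusters is not None \
        else np.ones(p, dtype=int)
    mod = _modularity(np.where(bundle.edge_indicator, bundle.similarity,
                               0.0), np.asarray(labels))

    g = nx.Graph()
    g.add_nodes_from(range(p))
    g.add_edges_from(zip(*np.nonzero(np.triu(bundle.edge_indicator, 1))))
    vconn = int(nx.node_connectivity(g)) if p > 1 else 0
    econn = int(nx.edge_connectivity(g)) if p > 1 else 0

    return GlobalMetrics(avg_path, cc, mod, vconn, econn, density, notes)


def analyze_network(bundle: AdjacencyBundle,
                    weighted: Optional[bool] = None,
                    cluster_method: str = "greedy_modularity",
                    cluster_params: Optional[dict] = None,
                    hub_measures: Sequence[str] = ("eigenvector",),
                    hub_method: str = "empirical_quantile",
                    hub_q: float = 0.95,
                    include_betweenness: bool = True) -> NetworkProperties:
    """One-call characterization: centralities, hubs, clusters, globals."""
    cent = centralities(bundle, weighted=weighted,
                        include_betweenness=include_betweenness)
    if bundle.edge_indicator.any():
        hubs = detect_hubs(cent, measures=hub_measures, method=hub_method,
                           q=hub_q)
        clusters = cluster_nodes(bundle, method=cluster_method,
                                 **(cluster_params or {}))
    else:
        hubs = []
        clusters = ClusterAssignment(list(bundle.node_ids),
                                     np.zeros(bundle.n_nodes, dtype=int),
                                     cluster_method)
    gm = global_metrics(bundle, clusters, weighted=weighted)
    return NetworkProperties(cent, hubs, clusters, gm)
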