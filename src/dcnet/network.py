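"""Functional-connectivity networks and degree centrality.

Pearson correlation matrices are binarized by sparsity: at sparsity S the
K = round(S * g(g-1)/2) strongest correlations become edges, giving every
subject a network with exactly the same edge budget so nodal degree values
are comparable across subjects.  Degree centrality of node i is the count of
its direct connections, C_D(N_i) = sum_j d_ij (i != j).  A sparsity sweep
(default 0.05 to 0.40 in steps of 0.01, 36 networks) plus efficiency and
small-world diagnostics support the choice of the reporting threshold
(default 0.30).
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)


@dataclass
class FCMatrix:
    """Symmetric g x g Pearson correlation matrix (diagonal 1)."""

    r: np.ndarray
    g: int


@dataclass
class BinaryNetwork:
    """Undirected binary adjacency at a given sparsity, with its exact edge
    budget K = round(S * g(g-1)/2)."""

    adjacency: np.ndarray
    sparsity: float
    edge_count: int


@dataclass
class DCTable:
    """Subjects x nodes degree-centrality matrix at one sparsity."""

    values: np.ndarray  # int, n_subjects x g
    sparsity: float
    subject_ids: list[str]
    node_labels: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids, columns=self.node_labels)


def default_node_labels(g: int) -> list[str]:
    return [f"BNA-{i + 1:03d}" for i in range(g)]


def compute_fc(series: np.ndarray) -> FCMatrix:
    """Pearson correlation between every pair of ROI time series."""
    series = np.asarray(series, dtype=float)
    if series.ndim != 2 or series.shape[0] < 3:
        raise ValueError("series must be T x g with T >= 3")
    sd = series.std(axis=0)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise ValueError(
            f"constant time series at node index {constant[0]}: correlation undefined"
        )
    r = np.corrcoef(series, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return FCMatrix(r=r, g=series.shape[1])


def threshold_by_sparsity(fc: FCMatrix, sparsity: float) -> BinaryNetwork:
    """Keep the K strongest correlations as edges, K = round(S * g(g-1)/2).

    Edges are ranked by signed correlation (positive end retained).  Ties at
    the boundary are broken by ascending (i, j) order so K is exact and the
    result deterministic; consequently networks are nested across an
    increasing sparsity sweep.
    """
    if not 0 < sparsity < 1:
        raise ValueError("sparsity must lie strictly between 0 and 1")
    g = fc.g
    iu, ju = np.triu_indices(g, k=1)
    vals = fc.r[iu, ju]
    k = int(round(sparsity * vals.size))
    adj = np.zeros((g, g), dtype=np.int8)
    if k > 0:
        order = np.lexsort((ju, iu, -vals))[:k]
        adj[iu[order], ju[order]] = 1
        adj = adj + adj.T  # edges live in the upper triangle only
    return BinaryNetwork(adjacency=adj, sparsity=sparsity, edge_count=k)


def sparsity_sweep(
    fc: FCMatrix, s_min: float = 0.05, s_max: float = 0.40, step: float = 0.01
) -> list[BinaryNetwork]:
    """One binary network per threshold from s_min to s_max inclusive."""
    if s_min > s_max:
        raise ValueError("s_min must not exceed s_max")
    n = int(round((s_max - s_min) / step)) + 1
    thresholds = np.round(s_min + step * np.arange(n), 10)
    return [threshold_by_sparsity(fc, float(s)) for s in thresholds]


def degree_centrality(net: BinaryNetwork) -> np.ndarray:
    """C_D(N_i): number of direct connections of each node (self excluded)."""
    return net.adjacency.sum(axis=1).astype(int)


def _pairwise_distances(adj: np.ndarray) -> np.ndarray:
    return shortest_path(csr_matrix(adj), method="D", unweighted=True)


def global_efficiency(net: BinaryNetwork | np.ndarray) -> float:
    """Mean over ordered node pairs of 1 / shortest path length
    (disconnected pairs contribute 0)."""
    adj = net.adjacency if isinstance(net, BinaryNetwork) else np.asarray(net)
    g = adj.shape[0]
    if g < 2 or adj.sum() == 0:
        return 0.0
    d = _pairwise_distances(adj)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (g * (g - 1)))


def local_efficiency(net: BinaryNetwork | np.ndarray) -> float:
    """Mean over nodes of the global efficiency of each node's
    neighbour-induced subgraph (nodes with fewer than 2 neighbours
    contribute 0)."""
    adj = net.adjacency if isinstance(net, BinaryNetwork) else np.asarray(net)
    g = adj.shape[0]
    if g == 0:
        return 0.0
    total = 0.0
    for i in range(g):
        nbrs = np.flatnonzero(adj[i])
        if nbrs.size < 2:
            continue
        total += global_efficiency(adj[np.ix_(nbrs, nbrs)])
    return total / g


def _to_igraph(adj: np.ndarray):
    import igraph as ig

    iu, ju = np.nonzero(np.triu(adj, k=1))
    return ig.Graph(n=adj.shape[0], edges=list(zip(iu.tolist(), ju.tolist())))


def _clustering_and_path(graph) -> tuple[float, float]:
    """Average local clustering coefficient (zero for degree < 2 nodes) and
    characteristic path length on the graph's largest connected component."""
    c = graph.transitivity_avglocal_undirected(mode="zero")
    comp = graph.connected_components()
    giant = graph if len(comp) == 1 else comp.giant()
    l = giant.average_path_length(directed=False)
    return float(c), float(l)


def small_world_sigma(
    net: BinaryNetwork, n_nulls: int = 20, seed: int = 0
) -> tuple[float, float, float]:
    """Small-world coefficient sigma = (C/C_rand) / (L/L_rand) against
    degree-preserving (Maslov-Sneppen) rewired nulls, 10 * |E| swap attempts
    per null.  Returns (sigma, C, L); computed on the largest component when
    the network is disconnected."""
    import igraph as ig

    adj = net.adjacency
    if net.edge_count < 2:
        return float("nan"), 0.0, float("nan")
    graph = _to_igraph(adj)
    c_obs, l_obs = _clustering_and_path(graph)
    ig.set_random_number_generator(random.Random(seed))
    c_rand = np.empty(n_nulls)
    l_rand = np.empty(n_nulls)
    for k in range(n_nulls):
        null = graph.copy()
        null.rewire(n=10 * net.edge_count)
        c_rand[k], l_rand[k] = _clustering_and_path(null)
    cr, lr = c_rand.mean(), l_rand.mean()
    if cr == 0 or lr == 0 or not np.isfinite(l_obs):
        return float("nan"), c_obs, l_obs
    return float((c_obs / cr) / (l_obs / lr)), c_obs, l_obs


def threshold_diagnostics(
    fc: FCMatrix,
    sweep: list[BinaryNetwork],
    n_nulls: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-threshold integrity and small-world diagnostics.

    Columns: sparsity, edge_count, n_components, global_efficiency,
    local_efficiency, clustering, path_length, sigma.  Disconnected networks
    are reported (component count > 1) and sigma is computed on the largest
    component with a logged note.
    """
    rows = []
    for net in sweep:
        n_comp = int(connected_components(csr_matrix(net.adjacency))[0])
        if n_comp > 1:
            logger.info(
                "sparsity %.2f: %d components; sigma computed on largest",
                net.sparsity,
                n_comp,
            )
        sigma, c_obs, l_obs = small_world_sigma(net, n_nulls=n_nulls, seed=seed)
        rows.append(
            {
                "sparsity": net.sparsity,
                "edge_count": net.edge_count,
                "n_components": n_comp,
                "global_efficiency": global_efficiency(net),
                "local_efficiency": local_efficiency(net),
                "clustering": c_obs,
                "path_length": l_obs,
                "sigma": sigma,
            }
        )
    return pd.DataFrame(rows)


def build_dc_table(
    series_by_subject: dict[str, np.ndarray],
    sparsity: float = 0.30,
    node_labels: list[str] | None = None,
) -> DCTable:
    """Per-subject FC -> sparsity threshold -> degree centrality, assembled
    into a subjects x nodes table.  Subjects whose FC cannot be computed
    (constant node series) are dropped with a logged reason."""
    ids, rows = [], []
    g = None
    for sid, series in series_by_subject.items():
        try:
            fc = compute_fc(series)
        except ValueError as exc:
            logger.warning("dropping subject %s: %s", sid, exc)
            continue
        g = fc.g
        net = threshold_by_sparsity(fc, sparsity)
        rows.append(degree_centrality(net))
        ids.append(sid)
    if not rows:
        raise ValueError("no subject yielded a valid FC matrix")
    labels = node_labels if node_labels is not None else default_node_labels(g)
    return DCTable(
        values=np.vstack(rows), sparsity=sparsity, subject_ids=ids, node_labels=labels
    )


class DegreeCentrality(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer: list of cleaned T' x g series -> n x g
    integer degree-centrality features at a fixed sparsity."""

    def __init__(self, sparsity: float = 0.30):
        self.sparsity = sparsity

    def fit(self, X, y=None):
        self.n_nodes_ = int(np.asarray(X[0]).shape[1])
        self.node_labels_ = default_node_labels(self.n_nodes_)
        return self

    def transform(self, X):
        rows = []
        for series in X:
            net = threshold_by_sparsity(compute_fc(series), self.sparsity)
            rows.append(degree_centrality(net))
        return np.vstack(rows)
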