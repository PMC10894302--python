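"""Symptom profiling: k-means clustering and Louvain community detection.

Two complementary views of cohort structure are produced from the same
standardized feature matrix: a centroid-based k-means partition (Euclidean
distance, silhouette-selected k) and a graph view in which each subject is
linked to its k nearest neighbors (Minkowski p = 2, i.e. Euclidean;
default k_nn = 100) and communities are found by greedy modularity
(Louvain) optimization. The kNN graph doubles as the substrate for the
network-based drug recommender.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from transdx.features import FeatureMatrix

logger = logging.getLogger(__name__)

#: silhouette is O(n^2); above this size it is computed on a seeded subsample
SILHOUETTE_MAX_N = 10_000

#: two silhouettes closer than this are treated as tied
_SILHOUETTE_TIE_TOL = 1e-12


@dataclass
class SimilarityGraph:
    """Undirected kNN patient-similarity graph.

    Built as the union of every node's directed k_nn-nearest-neighbor
    list (so each node has degree >= k_nn's incoming/outgoing union, and
    never less than 1 for n > 1); no self loops.
    """

    node_ids: list[str]
    graph: nx.Graph
    k_nn: int
    p: float
    weighted: bool = False

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)


@dataclass
class ClusterAssignment:
    """Per-subject cluster labels from one method.

    Labels are contiguous integers from 0. For Louvain they are ordered
    by descending community size (ties by smallest member position).
    """

    method: str  # "kmeans" or "louvain"
    subject_ids: list[str]
    labels: np.ndarray
    parameters: dict = field(default_factory=dict)
    quality: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.subject_ids):
            raise ValueError("labels and subject_ids disagree in length")
        uniq = np.unique(self.labels)
        if len(uniq) and (uniq.min() < 0 or not np.array_equal(uniq, np.arange(len(uniq)))):
            raise ValueError("cluster ids must be contiguous from 0")

    @property
    def n_clusters(self) -> int:
        return int(len(np.unique(self.labels)))

    def label_of(self) -> dict[str, int]:
        return dict(zip(self.subject_ids, (int(x) for x in self.labels)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"subject_id": self.subject_ids, "method": self.method, "label": self.labels}
        )


def _safe_silhouette(
    values: np.ndarray, labels: np.ndarray, seed: int = 0, max_n: int = SILHOUETTE_MAX_N
) -> float:
    """Mean silhouette with degenerate-case conventions.

    Returns 0.0 when fewer than two distinct labels exist or all points
    coincide; singleton-cluster members contribute 0 (scikit-learn's
    convention). Above ``max_n`` points a seeded uniform subsample is
    scored instead (logged).
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        return 0.0
    if not np.any(values != values[0]):
        return 0.0
    n = len(labels)
    if n > max_n:
        logger.info("silhouette on %d-point subsample of %d", max_n, n)
        rng = np.random.default_rng(seed)
        idx = rng.choice(n, size=max_n, replace=False)
        values, labels = values[idx], labels[idx]
        if len(np.unique(labels)) < 2:
            return 0.0
    return float(silhouette_score(values, labels))


def relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Relabel integer labels contiguously from 0 by descending group
    size; ties broken by the group's first member position."""
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    order = sorted(
        uniq,
        key=lambda c: (-int((labels == c).sum()), int(np.flatnonzero(labels == c)[0])),
    )
    mapping = {old: new for new, old in enumerate(order)}
    return np.array([mapping[x] for x in labels], dtype=int)


def fit_kmeans(fm: FeatureMatrix, k: int, seed: int = 0, n_init: int = 10) -> ClusterAssignment:
    """Lloyd k-means with Euclidean distance and multiple restarts.

    Runs ``n_init`` seeded initializations and keeps the lowest-inertia
    solution; convergence at relative inertia change below 1e-4. The
    partition silhouette is recorded in ``quality``.
    """
    if not fm.standardized:
        raise ValueError("feature matrix must be standardized before clustering")
    n = fm.n_subjects
    if not 2 <= k < n:
        raise ValueError(f"k must satisfy 2 <= k < n (got k={k}, n={n})")
    km = KMeans(n_clusters=k, n_init=n_init, tol=1e-4, random_state=seed)
    labels = km.fit_predict(fm.values)
    sil = _safe_silhouette(fm.values, labels, seed=seed)
    return ClusterAssignment(
        method="kmeans",
        subject_ids=list(fm.subject_ids),
        labels=relabel_by_size(labels),
        parameters={"k": k, "n_init": n_init},
        quality={"silhouette": sil, "inertia": float(km.inertia_)},
        seed=seed,
    )


def select_k_by_silhouette(
    fm: FeatureMatrix, k_grid: list[int], seed: int = 0
) -> tuple[ClusterAssignment, pd.DataFrame]:
    """Sweep k over a grid and keep the silhouette-maximizing partition.

    Ties (within 1e-12) break toward smaller k. Returns the selected
    assignment and the full k -> silhouette audit table.
    """
    n = fm.n_subjects
    if not k_grid:
        raise ValueError("empty k grid")
    for k in k_grid:
        if not 2 <= k <= n - 1:
            raise ValueError(f"k={k} outside [2, n-1] with n={n}")
    rows = []
    best: ClusterAssignment | None = None
    for k in sorted(k_grid):
        assignment = fit_kmeans(fm, k, seed=seed)
        s = assignment.quality["silhouette"]
        rows.append({"k": k, "silhouette": s, "inertia": assignment.quality["inertia"]})
        if best is None or s > best.quality["silhouette"] + _SILHOUETTE_TIE_TOL:
            best = assignment
    table = pd.DataFrame(rows)
    assert best is not None
    return best, table


def _neighbor_lists(
    values: np.ndarray, node_ids: list[str], k_nn: int, p: float, chunk: int = 512
) -> list[np.ndarray]:
    """Indices of each row's k_nn nearest neighbors under Minkowski-p,
    ties broken by subject-id order; self excluded."""
    n = len(node_ids)
    id_rank = np.argsort(np.argsort(np.asarray(node_ids, dtype=object)))
    out: list[np.ndarray] = []
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d = cdist(values[start:stop], values, metric="minkowski", p=p)
        for local, i in enumerate(range(start, stop)):
            row = d[local].copy()
            row[i] = np.inf  # exclude self regardless of duplicate points
            order = np.lexsort((id_rank, row))
            out.append(order[:k_nn])
    return out


def build_knn_graph(
    fm: FeatureMatrix,
    k_nn: int = 100,
    p: float = 2,
    weighted: bool = False,
) -> SimilarityGraph:
    """Build the undirected kNN patient-similarity graph.

    Each subject is linked to its ``k_nn`` nearest neighbors under the
    Minkowski-``p`` distance (defaults 100 and 2); directed neighbor
    lists are symmetrized by union into a simple graph. Distance ties at
    the k_nn-th rank break by subject-id order. With ``weighted`` the
    edges carry weight 1 / (1 + distance); default is binary adjacency.
    """
    n = fm.n_subjects
    if k_nn >= n:
        raise ValueError(f"k_nn={k_nn} must be < n={n}")
    if k_nn < 1:
        raise ValueError("k_nn must be >= 1")
    node_ids = list(fm.subject_ids)
    neighbor_idx = _neighbor_lists(fm.values, node_ids, k_nn, p)
    g = nx.Graph()
    g.add_nodes_from(node_ids)
    if weighted:
        for i, nbrs in enumerate(neighbor_idx):
            d = cdist(fm.values[i : i + 1], fm.values[nbrs], metric="minkowski", p=p)[0]
            for j, dist in zip(nbrs, d):
                g.add_edge(node_ids[i], node_ids[j], weight=1.0 / (1.0 + dist))
    else:
        for i, nbrs in enumerate(neighbor_idx):
            g.add_edges_from((node_ids[i], node_ids[j]) for j in nbrs)
    return SimilarityGraph(node_ids=node_ids, graph=g, k_nn=k_nn, p=p, weighted=weighted)


def modularity_q(g: SimilarityGraph | nx.Graph, labels: dict[str, int]) -> float:
    """Newman modularity Q of a labeling: the within-community edge
    fraction minus its expectation under the degree-preserving null,
    Q = sum_c [ L_c / m - (d_c / 2m)^2 ]."""
    graph = g.graph if isinstance(g, SimilarityGraph) else g
    m = graph.number_of_edges()
    if m == 0:
        raise ValueError("modularity undefined for an edgeless graph")
    communities: dict[int, set] = {}
    for node, c in labels.items():
        communities.setdefault(c, set()).add(node)
    q = 0.0
    for members in communities.values():
        l_c = sum(1 for u, v in graph.edges(members) if v in members and u in members)
        d_c = sum(graph.degree(u) for u in members)
        q += l_c / m - (d_c / (2.0 * m)) ** 2
    return q


def louvain_partition(
    g: SimilarityGraph, resolution: float = 1.0, seed: int = 0
) -> ClusterAssignment:
    """Louvain community detection on the similarity graph.

    Greedy modularity optimization with node-aggregation passes until no
    further gain; deterministic given ``seed``. Communities are relabeled
    contiguously by descending size; the standard (resolution-1)
    modularity Q of the final labeling is recorded. Disconnected graphs
    are handled as-is (communities never span components); component
    count is logged.
    """
    if g.n_nodes == 0:
        raise ValueError("empty graph")
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    n_comp = nx.number_connected_components(g.graph)
    if n_comp > 1:
        logger.info("similarity graph has %d connected components", n_comp)
    weight = "weight" if g.weighted else None
    communities = nx.community.louvain_communities(
        g.graph, weight=weight, resolution=resolution, seed=seed
    )
    pos = {node: i for i, node in enumerate(g.node_ids)}
    raw = np.empty(g.n_nodes, dtype=int)
    for c, members in enumerate(communities):
        for node in members:
            raw[pos[node]] = c
    labels = relabel_by_size(raw)
    q = modularity_q(g, dict(zip(g.node_ids, labels)))
    return ClusterAssignment(
        method="louvain",
        subject_ids=list(g.node_ids),
        labels=labels,
        parameters={"resolution": resolution, "k_nn": g.k_nn, "p": g.p},
        quality={"modularity": q},
        seed=seed,
    )


def sweep_resolution(
    g: SimilarityGraph,
    fm: FeatureMatrix,
    grid: list[float],
    seed: int = 0,
) -> tuple[ClusterAssignment, pd.DataFrame]:
    """Sweep the Louvain resolution and pick the partition whose
    feature-space silhouette is largest (ties toward fewer communities,
    then smaller resolution). Returns the winner plus the audit table of
    resolution -> (n_communities, Q, silhouette)."""
    if not grid:
        raise ValueError("empty resolution grid")
    if list(fm.subject_ids) != g.node_ids:
        raise ValueError("feature matrix and graph cover different subjects")
    rows = []
    best: ClusterAssignment | None = None
    best_sil = -np.inf
    for gamma in sorted(grid):
        assignment = louvain_partition(g, resolution=gamma, seed=seed)
        sil = _safe_silhouette(fm.values, assignment.labels, seed=seed)
        assignment.quality["silhouette"] = sil
        rows.append(
            {
                "resolution": gamma,
                "n_communities": assignment.n_clusters,
                "modularity": assignment.quality["modularity"],
                "silhouette": sil,
            }
        )
        better = sil > best_sil + _SILHOUETTE_TIE_TOL
        tied = best is not None and abs(sil - best_sil) <= _SILHOUETTE_TIE_TOL
        if best is None or better or (tied and assignment.n_clusters < best.n_clusters):
            best, best_sil = assignment, sil
    assert best is not None
    return best, pd.DataFrame(rows)


def embed_2d(fm: FeatureMatrix, seed: int = 0) -> pd.DataFrame:
    """2-D UMAP embedding for visualization only.

    Deterministic given ``seed``; never consumed by downstream
    computation. Requires at least 10 subjects.
    """
    if not fm.standardized:
        raise ValueError("feature matrix must be standardized before embedding")
    if fm.n_subjects < 10:
        raise ValueError("embedding needs at least 10 subjects")
    import umap  # deferred: importing umap trips numba compilation

    coords = umap.UMAP(n_components=2, random_state=seed).fit_transform(fm.values)
    return pd.DataFrame(coords, index=fm.subject_ids, columns=["umap1", "umap2"])
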