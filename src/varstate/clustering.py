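"""Two-way clustering of variants in standardized feature space.

Variants live in a z-scored feature space; each is connected to its k
nearest neighbors (Euclidean distance, k = 6 by default) to form a
directed kNN graph.  Two partitioning routes are provided: seeded
restarted k-means ("kmeans2", the default) and community detection on the
kNN graph merged down to two groups ("knn_community").  The cluster with
the higher fraction of population-catalog variants is labeled benign-like;
the other, which collects the known activating anchors, pathogenic-like.
Enrichment of catalog membership is assessed with an exact test on the
2x2 table.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .scores import FeatureMatrix

BENIGN_LIKE = "benign_like"
PATHOGENIC_LIKE = "pathogenic_like"


class ClusterError(ValueError):
    pass


def _as_frame(matrix: FeatureMatrix | pd.DataFrame) -> pd.DataFrame:
    if isinstance(matrix, FeatureMatrix):
        return matrix.values
    return matrix


def build_knn_graph(
    z_matrix: FeatureMatrix | pd.DataFrame, k: int = 6, chunk: int = 2048
) -> nx.DiGraph:
    """Exact k-nearest-neighbor digraph by Euclidean distance.

    Each node points to its k nearest neighbors (self excluded); ties are
    broken toward the variant key earlier in row order, so the graph is
    deterministic.  k >= N is clamped to N - 1 with a warning attribute.
    """
    df = _as_frame(z_matrix)
    n = len(df)
    if n < 2:
        raise ClusterError("need at least 2 variants")
    if k <= 0:
        raise ClusterError(f"k must be positive, got {k}")
    clamped = False
    if k >= n:
        k = n - 1
        clamped = True
    X = df.to_numpy(dtype=float)
    keys = list(df.index)
    g = nx.DiGraph(k=k, clamped=clamped, metric="euclidean")
    g.add_nodes_from(keys)
    order = np.arange(n)
    for start in range(0, n, chunk):
        block = X[start : start + chunk]
        d = np.sqrt(((block[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
        for i_local in range(len(block)):
            i = start + i_local
            di = d[i_local].copy()
            di[i] = np.inf  # no self-edges
            nbrs = np.lexsort((order, di))[:k]
            for j in nbrs:
                g.add_edge(keys[i], keys[j], weight=float(di[j]))
    return g


@dataclass
class ClusterResult:
    """A two-way partition with centroids and optional benign/pathogenic
    labels.  Cluster ids are 1 and 2; in labeled reports benign_like is
    printed as Cluster 1."""

    assignment: pd.Series  # variant key -> {1, 2}
    centroids: dict[int, np.ndarray]  # in z-space
    features: list[str]
    method: str
    seed: int
    labels: Optional[dict[str, int]] = None  # {"benign_like": cid, ...}
    conflicts: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def sizes(self) -> dict[int, int]:
        vc = self.assignment.value_counts()
        return {int(c): int(vc.get(c, 0)) for c in (1, 2)}

    def members(self, cluster_id: int) -> list:
        return list(self.assignment.index[self.assignment == cluster_id])

    def cluster_of_label(self, label: str) -> int:
        if self.labels is None:
            raise ClusterError("result is not labeled yet")
        return self.labels[label]


def _order_clusters(raw: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Renumber raw {0,1} assignments to {1,2} deterministically: the
    cluster whose centroid is lexicographically smaller becomes 1."""
    c0 = X[raw == 0].mean(axis=0)
    c1 = X[raw == 1].mean(axis=0)
    first_is_1 = tuple(np.round(c0, 12)) <= tuple(np.round(c1, 12))
    out = np.where(raw == 0, 1 if first_is_1 else 2, 2 if first_is_1 else 1)
    return out


def partition_two_way(
    z_matrix: FeatureMatrix | pd.DataFrame,
    method: str = "kmeans2",
    seed: int = 0,
    k: int = 6,
) -> ClusterResult:
    """Partition variants into two non-empty clusters.

    "kmeans2": k-means with 25 seeded restarts on the z-scored matrix.
    "knn_community": Louvain communities on the undirected kNN graph,
    merged to two groups by iteratively joining the closest (size-weighted)
    community centroids.
    Deterministic given (method, seed).
    """
    df = _as_frame(z_matrix)
    X = df.to_numpy(dtype=float)
    n = len(df)
    if n < 2:
        raise ClusterError("need at least 2 variants")
    if np.allclose(X, X[0]):
        raise ClusterError("degenerate matrix: all rows identical")

    if method == "kmeans2":
        km = KMeans(n_clusters=2, n_init=25, random_state=seed)
        raw = km.fit_predict(X)
        meta = {"inertia": float(km.inertia_), "n_iter": int(km.n_iter_)}
    elif method == "knn_community":
        graph = build_knn_graph(df, k=k)
        und = graph.to_undirected()
        communities = nx.community.louvain_communities(und, seed=seed)
        communities = sorted((sorted(c) for c in communities), key=lambda c: c[0])
        idx_of = {key: i for i, key in enumerate(df.index)}
        groups = [np.array([idx_of[key] for key in c]) for c in communities]
        # hierarchical merge of community centroids down to 2 groups
        while len(groups) > 2:
            cents = [X[g].mean(axis=0) for g in groups]
            best, bd = None, np.inf
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    d = float(np.linalg.norm(cents[a] - cents[b]))
                    if d < bd - 1e-12:
                        bd, best = d, (a, b)
            a, b = best
            groups[a] = np.concatenate([groups[a], groups[b]])
            del groups[b]
        if len(groups) < 2 or len(groups[0]) == 0 or len(groups[1]) == 0:
            raise ClusterError("community merge yielded fewer than two groups")
        raw = np.zeros(n, dtype=int)
        raw[groups[1]] = 1
        meta = {"n_communities_initial": len(communities), "k": k}
    else:
        raise ClusterError(f"unknown method {method!r}")

    assign = _order_clusters(raw, X)
    series = pd.Series(assign, index=df.index, name="cluster")
    centroids = {
        cid: X[assign == cid].mean(axis=0) for cid in (1, 2)
    }
    if (assign == 1).sum() == 0 or (assign == 2).sum() == 0:
        raise ClusterError("empty cluster produced")
    return ClusterResult(
        assignment=series,
        centroids=centroids,
        features=list(df.columns),
        method=method,
        seed=seed,
        metadata=meta,
    )


def label_clusters(
    result: ClusterResult,
    catalog_flags: Mapping | pd.Series,
    anchor_variants: Sequence[str] = (),
) -> ClusterResult:
    """Assign benign-like / pathogenic-like labels to the two clusters.

    The cluster with the higher fraction of catalog-flagged variants is
    benign-like.  An exact tie falls back to the anchors (pathogenic-like =
    the cluster holding the strict majority of anchors) and errors if no
    anchors are available.  Anchors landing in the benign-like cluster are
    recorded in ``result.conflicts`` rather than silently resolved.
    """
    flags = pd.Series(catalog_flags).reindex(result.assignment.index).fillna(False)
    anchors = [a for a in anchor_variants if a in result.assignment.index]
    if not flags.any() and not anchors:
        raise ClusterError("need catalog flags or anchors to label clusters")
    frac = {}
    for cid in (1, 2):
        members = result.assignment == cid
        frac[cid] = float(flags[members].mean()) if members.any() else 0.0
    if math.isclose(frac[1], frac[2]):
        if not anchors:
            raise ClusterError(
                "catalog flags split evenly between clusters; supply anchors"
            )
        anchor_cl = [int(result.assignment[a]) for a in anchors]
        n2 = sum(1 for c in anchor_cl if c == 2)
        pathogenic = 2 if n2 * 2 > len(anchor_cl) else 1
        benign = 1 if pathogenic == 2 else 2
    else:
        benign = 1 if frac[1] > frac[2] else 2
        pathogenic = 2 if benign == 1 else 1
    labels = {BENIGN_LIKE: benign, PATHOGENIC_LIKE: pathogenic}
    conflicts = [
        a for a in anchors if int(result.assignment[a]) != pathogenic
    ]
    result.labels = labels
    result.conflicts = conflicts
    result.metadata = dict(result.metadata, flag_fraction=frac, n_anchors=len(anchors))
    return result


@dataclass
class ClusterSummary:
    """Per-cluster feature means/sds on the original (pre-z) scale."""

    means: pd.DataFrame  # index: cluster id, columns: features
    sds: pd.DataFrame
    sizes: dict[int, int]
    anchor_counts: dict[int, int]


def summarize_clusters(
    result: ClusterResult,
    original_matrix: FeatureMatrix | pd.DataFrame,
    anchor_variants: Sequence[str] = (),
) -> ClusterSummary:
    df = _as_frame(original_matrix)
    if not df.index.equals(result.assignment.index):
        df = df.reindex(result.assignment.index)
        if df.isna().any().any():
            raise ClusterError("original matrix does not cover all assigned variants")
    grouped = df.groupby(result.assignment)
    means = grouped.mean()
    sds = grouped.std(ddof=1)
    anchor_counts = {1: 0, 2: 0}
    for a in anchor_variants:
        if a in result.assignment.index:
            anchor_counts[int(result.assignment[a])] += 1
    return ClusterSummary(
        means=means, sds=sds, sizes=result.sizes, anchor_counts=anchor_counts
    )


@dataclass
class EnrichmentResult:
    """Exact-test enrichment of catalog membership across the two clusters.

    Table layout: rows = (flagged, unflagged), columns = (cluster 1,
    cluster 2); OR = (a*d)/(b*c) with a Haldane-Anscombe +0.5 applied to
    all cells only when one is zero.
    """

    table: np.ndarray  # 2x2 [[a, b], [c, d]]
    odds_ratio: float
    p_value: float
    enriched_cluster: int

    @property
    def a(self) -> int:
        return int(self.table[0, 0])


def enrichment_test(
    result: ClusterResult, catalog_flags: Mapping | pd.Series
) -> EnrichmentResult:
    flags = pd.Series(catalog_flags).reindex(result.assignment.index).fillna(False)
    in1 = result.assignment == 1
    a = int((flags & in1).sum())
    b = int((flags & ~in1).sum())
    c = int((~flags & in1).sum())
    d = int((~flags & ~in1).sum())
    return enrichment_from_table(a, b, c, d)


def enrichment_from_table(a: int, b: int, c: int, d: int) -> EnrichmentResult:
    """Exact two-sided test and odds ratio for a 2x2 flagged-by-cluster table."""
    table = np.array([[a, b], [c, d]], dtype=int)
    if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        raise ClusterError("degenerate 2x2 margins")
    if min(a, b, c, d) == 0:
        aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d))
    else:
        aa, bb, cc, dd = a, b, c, d
    odds = (aa * dd) / (bb * cc)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    frac1 = a / (a + c)
    frac2 = b / (b + d)
    enriched = 1 if frac1 >= frac2 else 2
    return EnrichmentResult(
        table=table, odds_ratio=float(odds), p_value=float(p), enriched_cluster=enriched
    )


def assign_new_variant(
    z_vector: np.ndarray | Sequence[float],
    labeled_result: ClusterResult,
) -> tuple[str, dict[str, float]]:
    """Nearest-centroid assignment of a z-scored query vector.

    Returns the benign_like/pathogenic_like label and the distance to both
    centroids; an exact tie yields ``"unclassified"``.
    """
    if labeled_result.labels is None:
        raise ClusterError("cluster result must be labeled before assignment")
    v = np.asarray(z_vector, dtype=float)
    if v.shape != labeled_result.centroids[1].shape:
        raise ClusterError(
            f"dimension mismatch: query {v.shape} vs centroid "
            f"{labeled_result.centroids[1].shape}"
        )
    dists = {}
    for label, cid in labeled_result.labels.items():
        dists[label] = float(np.linalg.norm(v - labeled_result.centroids[cid]))
    db, dp = dists[BENIGN_LIKE], dists[PATHOGENIC_LIKE]
    if db == dp:
        return "unclassified", dists
    return (BENIGN_LIKE if db < dp else PATHOGENIC_LIKE), dists


def export_network(
    graph: nx.DiGraph,
    labeled_result: ClusterResult,
    path: str | Path,
    origin: Optional[Mapping] = None,
    subsample: Optional[int] = None,
    seed: int = 0,
) -> nx.DiGraph:
    """Write the kNN graph with cluster/label/origin node attributes.

    GraphML when the path ends in .graphml, else an edge-list CSV with a
    sidecar node table.  ``subsample`` keeps a seeded random subset of
    nodes (with their induced edges) for display.
    """
    nodes = set(graph.nodes)
    if nodes != set(labeled_result.assignment.index):
        raise ClusterError("graph and cluster result node sets differ")
    g = graph.copy()
    origin = origin or {}
    for node in g.nodes:
        cid = int(labeled_result.assignment[node])
        g.nodes[node]["cluster"] = cid
        if labeled_result.labels is not None:
            inv = {v: k for k, v in labeled_result.labels.items()}
            g.nodes[node]["label"] = inv[cid]
        g.nodes[node]["origin"] = str(origin.get(node, "saturation"))
    if subsample is not None and subsample < g.number_of_nodes():
        rng = np.random.default_rng(seed)
        keep = rng.choice(sorted(g.nodes), size=subsample, replace=False)
        g = g.subgraph(keep).copy()
    path = Path(path)
    if path.suffix == ".graphml":
        nx.write_graphml(g, path)
    else:
        with path.open("w") as fh:
            fh.write("source\ttarget\tweight\n")
            for u, v, data in sorted(g.edges(data=True)):
                fh.write(f"{u}\t{v}\t{data.get('weight', 1.0):.6g}\n")
        nodes_path = path.with_suffix(path.suffix + ".nodes.tsv")
        with nodes_path.open("w") as fh:
            fh.write("node\tcluster\tlabel\torigin\n")
            for node in sorted(g.nodes):
                nd = g.nodes[node]
                fh.write(
                    f"{node}\t{nd['cluster']}\t{nd.get('label', '')}\t{nd['origin']}\n"
                )
    return g
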