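"""kNN graph, two-way partitioning, labeling, enrichment, assignment."""
from math import comb

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import varstate as vs
from varstate.clustering import ClusterError
from conftest import brute_force_knn


def _frame(X, keys=None):
    keys = keys or [f"v{i:03d}" for i in range(len(X))]
    return pd.DataFrame(np.asarray(X, dtype=float), index=keys)


def test_knn_graph_matches_brute_force_oracle():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(40, 4))
    df = _frame(X)
    g = vs.build_knn_graph(df, k=6)
    oracle = brute_force_knn(X, list(df.index), 6)
    for node in df.index:
        assert sorted(g.successors(node)) == sorted(oracle[node])
        assert g.out_degree(node) == 6


def test_knn_graph_clamps_k_and_rejects_bad_k():
    df = _frame(np.eye(3))
    g = vs.build_knn_graph(df, k=6)
    assert all(d == 2 for _, d in g.out_degree())
    assert g.graph["clamped"]
    with pytest.raises(ClusterError):
        vs.build_knn_graph(df, k=0)


def test_knn_graph_collinear_and_tie_rule():
    # middle point's single neighbor is the closer endpoint
    df = _frame([[0.0], [1.0], [3.0]], keys=["a", "b", "c"])
    g = vs.build_knn_graph(df, k=1)
    assert list(g.successors("b")) == ["a"]
    # duplicated points: tie broken toward the earlier key
    df2 = _frame([[0.0], [0.0], [0.0]], keys=["a", "b", "c"])
    g2 = vs.build_knn_graph(df2, k=1)
    assert list(g2.successors("b")) == ["a"]
    assert list(g2.successors("c")) == ["a"]
    assert not any(u == v for u, v in g2.edges)


def _two_gaussians(n1=60, n2=80, sep=8.0, seed=0, dim=3):
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [rng.normal(0.0, 1.0, size=(n1, dim)), rng.normal(sep, 1.0, size=(n2, dim))]
    )
    truth = np.array([0] * n1 + [1] * n2)
    return _frame(X), truth


@pytest.mark.parametrize("method", ["kmeans2", "knn_community"])
def test_partition_recovers_separated_gaussians(method):
    df, truth = _two_gaussians()
    res = vs.partition_two_way(df, method=method, seed=1)
    assert res.sizes[1] + res.sizes[2] == len(df)
    ari = adjusted_rand_score(truth, res.assignment.to_numpy())
    assert ari >= 0.99


def test_partition_duplicated_blocks_split_perfectly():
    block = np.arange(10)[:, None] * 0.01
    X = np.vstack([block, block + 10.0])
    res = vs.partition_two_way(_frame(X), seed=0)
    assert res.sizes == {1: 10, 2: 10}


@pytest.mark.parametrize("method", ["kmeans2", "knn_community"])
def test_partition_deterministic_given_seed(method):
    df, _ = _two_gaussians(seed=5)
    r1 = vs.partition_two_way(df, method=method, seed=7)
    r2 = vs.partition_two_way(df, method=method, seed=7)
    assert r1.assignment.equals(r2.assignment)
    assert r1.method == method and r1.seed == 7


def test_partition_rejects_degenerate():
    df = _frame(np.ones((5, 2)))
    with pytest.raises(ClusterError, match="identical"):
        vs.partition_two_way(df, seed=0)


def _labeled_result(flag_fracs=(0.9, 0.05), seed=0):
    df, truth = _two_gaussians(seed=seed)
    res = vs.partition_two_way(df, seed=seed)
    rng = np.random.default_rng(seed)
    flags = pd.Series(False, index=df.index)
    for cid, frac in zip((1, 2), flag_fracs):
        members = res.assignment.index[res.assignment == cid]
        flags[members] = rng.random(len(members)) < frac
    return df, res, flags


def test_label_clusters_by_flag_fraction():
    _, res, flags = _labeled_result()
    res = vs.label_clusters(res, flags)
    assert res.labels[vs.BENIGN_LIKE] == 1
    assert res.labels[vs.PATHOGENIC_LIKE] == 2


def test_label_clusters_anchor_conflicts_are_reported():
    _, res, flags = _labeled_result()
    benign_member = res.assignment.index[res.assignment == 1][0]
    path_member = res.assignment.index[res.assignment == 2][0]
    res = vs.label_clusters(res, flags, [benign_member, path_member])
    assert benign_member in res.conflicts
    assert path_member not in res.conflicts


def test_label_clusters_tie_needs_anchors():
    df, res, _ = _labeled_result()
    no_flags = pd.Series(False, index=df.index)
    with pytest.raises(ClusterError):
        vs.label_clusters(res, no_flags, [])
    anchor = res.assignment.index[res.assignment == 2][0]
    res = vs.label_clusters(res, no_flags, [anchor])
    assert res.labels[vs.PATHOGENIC_LIKE] == 2


def test_summary_means_recombine_to_global_mean():
    df, res, flags = _labeled_result(seed=2)
    summ = vs.summarize_clusters(res, df)
    n1, n2 = summ.sizes[1], summ.sizes[2]
    recombined = (summ.means.loc[1] * n1 + summ.means.loc[2] * n2) / (n1 + n2)
    np.testing.assert_allclose(recombined, df.mean(axis=0), atol=1e-9)


def test_summary_toy_mean():
    df = _frame([[2.0], [4.0], [10.0], [10.0]], keys=list("abcd"))
    res = vs.ClusterResult(
        assignment=pd.Series([1, 1, 2, 2], index=df.index),
        centroids={1: np.array([3.0]), 2: np.array([10.0])},
        features=["f"],
        method="manual",
        seed=0,
    )
    summ = vs.summarize_clusters(res, df)
    assert summ.means.loc[1, 0] == pytest.approx(3.0)


def exact_two_sided_p(a, b, c, d):
    """Brute-force enumeration of the hypergeometric support."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    denom = comb(n, c1)

    def prob(x):
        return comb(r1, x) * comb(n - r1, c1 - x) / denom

    p_obs = prob(a)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


def test_enrichment_or_from_printed_counts():
    """The catalog-by-cluster table 214/75/7345/14292 gives OR ~ 5.55."""
    res = vs.enrichment_from_table(214, 75, 7345, 14292)
    direct = (214 * 14292) / (75 * 7345)
    assert res.odds_ratio == pytest.approx(direct)
    assert res.odds_ratio == pytest.approx(5.55, abs=0.01)
    assert res.enriched_cluster == 1
    assert res.p_value < 1e-30


def test_enrichment_null_table():
    res = vs.enrichment_from_table(5, 5, 20, 20)
    assert res.odds_ratio == pytest.approx(1.0)
    assert res.p_value == pytest.approx(1.0)


def test_enrichment_haldane_on_zero_cell_and_exact_p():
    res = vs.enrichment_from_table(5, 0, 0, 5)
    assert np.isfinite(res.odds_ratio)
    assert res.odds_ratio == pytest.approx((5.5 * 5.5) / (0.5 * 0.5))
    assert res.p_value == pytest.approx(exact_two_sided_p(5, 0, 0, 5), rel=1e-9)


def test_enrichment_p_matches_enumeration_small_margins():
    rng = np.random.default_rng(1)
    for _ in range(40):
        a, b, c, d = rng.integers(0, 13, size=4)
        if min(a + b, c + d, a + c, b + d) == 0:
            continue
        res = vs.enrichment_from_table(int(a), int(b), int(c), int(d))
        assert res.p_value == pytest.approx(
            exact_two_sided_p(int(a), int(b), int(c), int(d)), rel=1e-9
        )


def test_enrichment_rejects_degenerate_margins():
    with pytest.raises(ClusterError):
        vs.enrichment_from_table(0, 0, 3, 4)


def test_assign_new_variant_centroid_and_tie():
    _, res, flags = _labeled_result()
    res = vs.label_clusters(res, flags)
    cp = res.centroids[res.labels[vs.PATHOGENIC_LIKE]]
    label, dists = vs.assign_new_variant(cp, res)
    assert label == vs.PATHOGENIC_LIKE
    assert dists[vs.PATHOGENIC_LIKE] == pytest.approx(0.0)
    mid = (res.centroids[1] + res.centroids[2]) / 2
    label, _ = vs.assign_new_variant(mid, res)
    assert label == "unclassified"
    with pytest.raises(ClusterError, match="dimension"):
        vs.assign_new_variant(np.zeros(99), res)


def test_export_network_graphml_and_subsample(tmp_path):
    df, res, flags = _labeled_result()
    res = vs.label_clusters(res, flags)
    g = vs.build_knn_graph(df, k=6)
    out = tmp_path / "net.graphml"
    kept = vs.export_network(g, res, out, subsample=50, seed=4)
    assert kept.number_of_nodes() == 50
    back = nx.read_graphml(out)
    assert back.number_of_nodes() == 50
    node = next(iter(back.nodes))
    assert "cluster" in back.nodes[node] and "label" in back.nodes[node]
    # same seed, same subsample
    kept2 = vs.export_network(g, res, out, subsample=50, seed=4)
    assert set(kept.nodes) == set(kept2.nodes)


def test_export_edge_list_roundtrip(tmp_path):
    df, res, flags = _labeled_result()
    res = vs.label_clusters(res, flags)
    g = vs.build_knn_graph(df, k=3)
    out = tmp_path / "net.tsv"
    vs.export_network(g, res, out)
    edges = pd.read_csv(out, sep="\t")
    assert len(edges) == g.number_of_edges()
    rebuilt = set(zip(edges["source"], edges["target"]))
    assert rebuilt == set(g.edges)
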