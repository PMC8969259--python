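import numpy as np
import pytest

from afclust.binning import (
    attach_weight,
    bin_raw_cluster,
    bin_score,
    intra_bin_weight,
    order_vertices,
)
from afclust.graph import ClusterGraph, contract, init_graph

from conftest import random_similarity


# ------------------------------------------------------------------ oracle
# An independent replay of the binning rule computed purely from the
# primitive similarity matrix W0 and the vertex membership lists: every
# I_bin / I value is a plain mean over primitive pairs, and the vertex
# ordering re-derives edge weights and cluster sizes from the same source.

def _prims(graph, vs):
    return np.concatenate([graph.members[v] for v in vs])


def _pmean_within(graph, B):
    prims = _prims(graph, B)
    if prims.size == 1:
        return 1.0
    vals = [graph.W0[u, v] for ai, u in enumerate(prims) for v in prims[ai + 1:]]
    return float(np.mean(vals))


def _pmean_cross(graph, B, t):
    pb, pt = _prims(graph, B), graph.members[t]
    return float(np.mean([[graph.W0[u, v] for v in pt] for u in pb]))


def oracle_order(graph, raw_cluster):
    vs = sorted(raw_cluster)
    if len(vs) == 1:
        return vs
    edges = sorted(
        ((u, v) for ai, u in enumerate(vs) for v in vs[ai + 1:]),
        key=lambda e: (-_pmean_cross(graph, [e[0]], e[1]), e[0], e[1]),
    )
    J, seen = [], set()
    for u, v in edges:
        if u not in seen and v not in seen:
            ru, rv = len(graph.members[u]), len(graph.members[v])
            pair = (u, v) if ru >= rv else (v, u)
            J.extend(pair)
            seen.update(pair)
        elif u not in seen:
            J.append(u)
            seen.add(u)
        elif v not in seen:
            J.append(v)
            seen.add(v)
    return J


def oracle_bins(graph, raw_cluster, gamma_low):
    J = oracle_order(graph, raw_cluster)
    bins = [[J[0]]]
    for v_t in J[1:]:
        scores = [2 * _pmean_cross(graph, B, v_t) - _pmean_within(graph, B) - gamma_low for B in bins]
        best = int(np.argmax(scores))
        if scores[best] > 0:
            bins[best].append(v_t)
        else:
            bins.append([v_t])
    return bins


def _random_contracted_graph(rng, n_prims=None):
    n = n_prims or int(rng.integers(6, 21))
    g = init_graph(random_similarity(rng, n))
    labels = rng.integers(0, max(2, n // 2), size=n)
    clusters = [np.flatnonzero(labels == lab).tolist() for lab in np.unique(labels)]
    return contract(g, clusters)


# ------------------------------------------------------------------- tests

def test_larger_rho_endpoint_enters_first():
    g = init_graph(random_similarity(np.random.default_rng(0), 4))
    g = contract(g, [[0, 1, 2], [3]])  # rho = (3, 1)
    assert order_vertices([0, 1], g) == [0, 1]
    # and the other way around when rho order flips
    g2 = init_graph(random_similarity(np.random.default_rng(0), 4))
    g2 = contract(g2, [[0], [1, 2, 3]])  # rho = (1, 3)
    assert order_vertices([0, 1], g2) == [1, 0]


def test_three_vertex_order_follows_descending_edges():
    W = np.array(
        [[1.0, 0.9, 0.8], [0.9, 1.0, 0.7], [0.8, 0.7, 1.0]]
    )
    g = init_graph(W)
    # w01 > w02 > w12; equal rho so the smaller index of the top edge leads
    assert order_vertices([0, 1, 2], g) == [0, 1, 2]


@pytest.mark.parametrize("seed", range(8))
def test_ordering_matches_independent_sorter(seed):
    rng = np.random.default_rng(seed)
    g = _random_contracted_graph(rng)
    k = min(6, g.n_vertices)
    cluster = sorted(rng.choice(g.n_vertices, size=k, replace=False).tolist())
    assert order_vertices(cluster, g) == oracle_order(g, cluster)


def test_intra_bin_weight_cases():
    W = np.array([[1.0, 0.9], [0.9, 1.0]])
    g = init_graph(W)
    g_c = contract(g, [[0, 1]])
    g_c.W[0, 0] = 0.93  # singleton bin takes the vertex weight verbatim
    assert intra_bin_weight([0], g_c) == pytest.approx(0.93)
    # two rho-1 vertices: the rho(rho-1)/2 self terms vanish
    assert intra_bin_weight([0, 1], g) == pytest.approx(0.9)


def test_intra_bin_weight_equals_primitive_pair_mean():
    rng = np.random.default_rng(4)
    g0 = init_graph(random_similarity(rng, 5))
    g = contract(g0, [[0, 1], [2, 3, 4]])  # rho = (2, 3)
    assert intra_bin_weight([0, 1], g) == pytest.approx(_pmean_within(g, [0, 1]), abs=1e-12)


def test_attach_weight_cases():
    rng = np.random.default_rng(5)
    g0 = init_graph(random_similarity(rng, 6))
    g = contract(g0, [[0, 1], [2, 3, 4], [5]])
    # one-vertex bin: I is just the edge weight
    assert attach_weight([0], 1, g) == pytest.approx(g.W[0, 1])
    # rho-weighted mean equals the primitive-pair mean
    assert attach_weight([0, 1], 2, g) == pytest.approx(_pmean_cross(g, [0, 1], 2), abs=1e-12)
    with pytest.raises(ValueError):
        attach_weight([0, 1], 0, g)


def test_bin_score_is_eq3():
    W = np.ones((2, 2))
    g = init_graph(W)
    # I = I_bin = 1 (vertex weight 1, edge weight 1): Q = 2 - 1 - 0.8
    assert bin_score([0], 1, g, 0.8) == pytest.approx(0.2)


def test_pairs_merge_or_split_on_the_strict_zero_boundary():
    W = np.array([[1.0, 0.95], [0.95, 1.0]])
    g = init_graph(W)
    assert bin_raw_cluster([0, 1], g, 0.8) == [[0, 1]]  # Q = 0.1 > 0
    W2 = np.array([[1.0, 0.85], [0.85, 1.0]])
    g2 = init_graph(W2)
    assert bin_raw_cluster([0, 1], g2, 0.8) == [[0], [1]]  # Q = -0.1
    W3 = np.array([[1.0, 0.9], [0.9, 1.0]])
    g3 = init_graph(W3)
    # Q = 2*0.9 - 1 - 0.8 = 0 exactly: strict inequality, so a new bin
    assert bin_raw_cluster([0, 1], g3, 0.8) == [[0], [1]]


@pytest.mark.parametrize("seed", range(10))
def test_binning_matches_step_by_step_replay(seed):
    rng = np.random.default_rng(1000 + seed)
    g = _random_contracted_graph(rng)
    k = min(8, g.n_vertices)
    cluster = sorted(rng.choice(g.n_vertices, size=k, replace=False).tolist())
    gamma_low = float(rng.uniform(0.3, 0.8))
    bins = bin_raw_cluster(cluster, g, gamma_low)
    assert bins == oracle_bins(g, cluster, gamma_low)
    # bins partition the raw cluster
    flat = sorted(v for b in bins for v in b)
    assert flat == cluster


def test_binning_deterministic():
    rng = np.random.default_rng(9)
    g = _random_contracted_graph(rng)
    cluster = list(range(g.n_vertices))
    assert bin_raw_cluster(cluster, g, 0.6) == bin_raw_cluster(cluster, g, 0.6)
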