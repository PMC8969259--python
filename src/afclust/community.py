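"""Raw-cluster detection by Constant Potts Model (CPM) maximization.

The CPM quality of a partition of the complete weighted graph is

    q = sum over intra-cluster vertex pairs (i < j) of (w_ij - gamma)

so an all-singleton partition scores 0 and gamma lower-bounds the average
intra-cluster edge weight of every vertex in a non-singleton cluster.
Detection runs the Leiden algorithm (seeded) and then a deterministic
single-vertex local-move refinement, so the returned partition always has
q >= 0, is locally optimal, and never co-clusters a forbidden pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np

from .graph import ClusterGraph

_MOVE_TOL = 1e-12


@dataclass
class Partition:
    """Vertex-to-raw-cluster assignment; labels are 0..K-1 in order of
    first appearance."""

    sigma: np.ndarray

    def __post_init__(self):
        self.sigma = _canonical_labels(np.asarray(self.sigma, dtype=np.int64))

    @property
    def clusters(self) -> list[list[int]]:
        out: dict[int, list[int]] = {}
        for v, lab in enumerate(self.sigma):
            out.setdefault(int(lab), []).append(v)
        return [out[k] for k in sorted(out)]


def _canonical_labels(sigma: np.ndarray) -> np.ndarray:
    mapping: dict[int, int] = {}
    out = np.empty_like(sigma)
    for i, lab in enumerate(sigma):
        out[i] = mapping.setdefault(int(lab), len(mapping))
    return out


def cpm_quality(graph: ClusterGraph, partition: Partition, gamma: float) -> float:
    """CPM score of a partition.  Vertex weights (the diagonal) are not
    edges and contribute nothing."""
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must be in [0, 1], got {gamma}")
    sigma = partition.sigma
    if sigma.shape[0] != graph.n_vertices:
        raise ValueError("partition does not match graph")
    q = 0.0
    for lab in np.unique(sigma):
        idx = np.flatnonzero(sigma == lab)
        if idx.size < 2:
            continue
        sub = graph.W[np.ix_(idx, idx)]
        n_pairs = idx.size * (idx.size - 1) / 2
        q += (np.triu(sub, 1).sum()) - gamma * n_pairs
    return float(q)


def _local_moves(W: np.ndarray, gamma: float, sigma: np.ndarray) -> np.ndarray:
    """Greedy single-vertex moves (to an existing cluster or a new
    singleton) until none strictly increases q.  Deterministic: vertices in
    index order, ties keep the current assignment / prefer the smaller
    candidate label."""
    n = W.shape[0]
    sigma = sigma.copy()
    improved = True
    while improved:
        improved = False
        for v in range(n):
            cur = sigma[v]
            labels = np.unique(sigma)
            # score of v's edges into each cluster (excluding v itself)
            mask_self = np.arange(n) != v
            best_lab, best_gain = cur, 0.0
            cur_idx = np.flatnonzero((sigma == cur) & mask_self)
            cur_score = (W[v, cur_idx] - gamma).sum() if cur_idx.size else 0.0
            for lab in labels:
                if lab == cur:
                    continue
                idx = np.flatnonzero((sigma == lab) & mask_self)
                gain = (W[v, idx] - gamma).sum() - cur_score
                if gain > best_gain + _MOVE_TOL:
                    best_gain, best_lab = gain, lab
            # moving out to a fresh singleton
            gain = -cur_score
            if gain > best_gain + _MOVE_TOL:
                best_gain, best_lab = gain, int(sigma.max()) + 1
            if best_lab != cur:
                sigma[v] = best_lab
                improved = True
    return sigma


def detect_raw_clusters(graph: ClusterGraph, gamma: float, rng_seed: int = 0) -> Partition:
    """Partition the graph into raw clusters maximizing CPM at ``gamma``.

    Runs seeded Leiden (CPM quality, until stable) followed by the local
    refinement above; asserts q >= 0 and that no forbidden pair is
    co-clustered.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must be in [0, 1], got {gamma}")
    n = graph.n_vertices
    if n == 1:
        return Partition(np.zeros(1, dtype=np.int64))

    iu, jv = np.triu_indices(n, k=1)
    g = ig.Graph(n=n, edges=list(zip(iu.tolist(), jv.tolist())))
    weights = graph.W[iu, jv].tolist()
    part = leidenalg.find_partition(
        g,
        leidenalg.CPMVertexPartition,
        weights=weights,
        resolution_parameter=gamma,
        n_iterations=-1,
        seed=int(rng_seed),
    )
    sigma = _local_moves(graph.W, gamma, np.asarray(part.membership, dtype=np.int64))
    partition = Partition(sigma)

    q = cpm_quality(graph, partition, gamma)
    if q < -_MOVE_TOL:
        raise RuntimeError(f"CPM partition has negative quality {q}")
    for pair in graph.forbidden:
        u, v = tuple(pair)
        if partition.sigma[u] == partition.sigma[v]:
            raise RuntimeError(f"forbidden pair ({u}, {v}) co-clustered")
    return partition
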