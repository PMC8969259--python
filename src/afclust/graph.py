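"""The complete weighted cluster graph and its contraction.

Vertices represent validated clusters of primitive sequences.  The matrix
``W`` carries edge weights off the diagonal and vertex weights (average
intra-cluster similarity) on the diagonal; ``rho`` counts the primitive
sequences under each vertex.  Sibling clusters split from one raw cluster
are recorded as *forbidden* pairs and barred from co-clustering by a large
negative sentinel edge weight ``-|V|**2``.

Every vertex and non-forbidden edge weight equals the arithmetic mean of
the corresponding primitive-pair similarities.  Contraction therefore
recomputes weights directly from the primitive similarity matrix ``W0``
(kept on the graph), which is exactly equivalent to the rho-weighted
averaging of the previous level and keeps the forbidden sentinel out of
all averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np


@dataclass
class ClusterGraph:
    W: np.ndarray                      # current weights; diag = vertex weights
    rho: np.ndarray                    # primitive count per vertex
    members: list[np.ndarray]          # primitive indices per vertex
    forbidden: set[frozenset]          # unordered current-vertex pairs
    W0: np.ndarray                     # primitive similarity matrix

    @property
    def n_vertices(self) -> int:
        return self.W.shape[0]

    @property
    def n_primitives(self) -> int:
        return self.W0.shape[0]

    def is_forbidden(self, i: int, j: int) -> bool:
        return frozenset((i, j)) in self.forbidden


def init_graph(W0: np.ndarray) -> ClusterGraph:
    """Initial graph: every primitive sequence is a singleton vertex with
    vertex weight 1 and ``rho = 1``; no forbidden pairs."""
    W0 = np.asarray(W0, dtype=float)
    if W0.ndim != 2 or W0.shape[0] != W0.shape[1]:
        raise ValueError("similarity matrix must be square")
    if not np.allclose(W0, W0.T, atol=1e-12):
        raise ValueError("similarity matrix must be symmetric")
    if not np.allclose(np.diag(W0), 1.0):
        raise ValueError("similarity matrix diagonal must be 1")
    n = W0.shape[0]
    return ClusterGraph(
        W=W0.copy(),
        rho=np.ones(n, dtype=np.int64),
        members=[np.array([i]) for i in range(n)],
        forbidden=set(),
        W0=W0,
    )


def _check_partition(clusters: Sequence[Iterable[int]], n: int) -> None:
    seen = np.zeros(n, dtype=bool)
    count = 0
    for c in clusters:
        for v in c:
            if seen[v]:
                raise ValueError(f"vertex {v} appears in more than one cluster")
            seen[v] = True
            count += 1
    if count != n:
        raise ValueError("clusters do not partition the vertex set")


def contract(
    graph: ClusterGraph,
    clusters: Sequence[Iterable[int]],
    sibling_groups: Sequence[Sequence[int]] = (),
) -> ClusterGraph:
    """Replace each cluster of vertices by one vertex.

    New vertex weights are the mean similarity over all primitive pairs
    inside the cluster (1 for a single primitive); new edge weights the
    mean over all cross-cluster primitive pairs.  ``sibling_groups`` lists
    clusters that were split from the same raw cluster: all their pairs,
    plus every pair inheriting forbidden status from the previous level,
    get the ``-|V'|**2`` sentinel weight.
    """
    clusters = [np.fromiter(c, dtype=np.int64) for c in clusters]
    n_old = graph.n_vertices
    _check_partition(clusters, n_old)
    m = len(clusters)

    new_members = [np.sort(np.concatenate([graph.members[v] for v in c])) for c in clusters]
    new_rho = np.array([mem.size for mem in new_members], dtype=np.int64)

    # primitive-pair sums via the indicator matrix: S[i, j] = sum of W0 over
    # members_i x members_j (diagonal blocks double-count ordered pairs)
    M = np.zeros((m, graph.n_primitives))
    for i, mem in enumerate(new_members):
        M[i, mem] = 1.0
    S = M @ graph.W0 @ M.T

    rr = new_rho.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        newW = S / np.outer(rr, rr)
        intra_pairs = rr * (rr - 1.0) / 2.0
        diag = np.where(intra_pairs > 0, (np.diag(S) - rr) / 2.0 / np.where(intra_pairs > 0, intra_pairs, 1.0), 1.0)
    np.fill_diagonal(newW, diag)

    # forbidden ledger: heredity from the previous level + new sibling pairs
    vertex_to_cluster = np.empty(n_old, dtype=np.int64)
    for ci, c in enumerate(clusters):
        vertex_to_cluster[c] = ci
    new_forbidden: set[frozenset] = set()
    for pair in graph.forbidden:
        u, v = tuple(pair)
        cu, cv = vertex_to_cluster[u], vertex_to_cluster[v]
        if cu == cv:
            raise RuntimeError(f"forbidden pair {pair} was merged into one cluster")
        new_forbidden.add(frozenset((int(cu), int(cv))))
    for group in sibling_groups:
        group = list(group)
        for a in range(len(group)):
            for b in range(a + 1, len(group)):
                new_forbidden.add(frozenset((int(group[a]), int(group[b]))))

    sentinel = -float(m) ** 2
    for pair in new_forbidden:
        u, v = tuple(pair)
        newW[u, v] = newW[v, u] = sentinel

    return ClusterGraph(W=newW, rho=new_rho, members=new_members,
                        forbidden=new_forbidden, W0=graph.W0)
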