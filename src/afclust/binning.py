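"""Adaptive binning of raw clusters into validated graph clusters.

Each raw cluster is processed independently.  Its vertices are ordered by
descending intra-cluster edge weight (edge endpoints enter the list as
their edges are visited), then assigned one by one: a candidate vertex
``v_t`` may join an existing bin ``B`` only when the cluster separation
``I_bin(B) - I(B, v_t)`` is smaller than the adaptive cut-off
``I(B, v_t) - gamma_low``, i.e. when the score

    Q(B, v_t) = 2 * I(B, v_t) - I_bin(B) - gamma_low

is strictly positive.  ``I_bin`` is the rho-weighted mean intra-bin
similarity (a vertex's own weight counts with multiplicity
``rho * (rho - 1) / 2``, cross-vertex edges with ``rho_i * rho_j``) and
``I`` is the rho-weighted mean edge weight between ``v_t`` and the bin.
The candidate joins the bin with the highest positive score, or seeds a
new bin when none is positive.
"""

from __future__ import annotations

from typing import Sequence

from .graph import ClusterGraph

_TIE_TOL = 1e-12


def order_vertices(raw_cluster: Sequence[int], graph: ClusterGraph) -> list[int]:
    """Vertex list J: endpoints of intra-cluster edges in descending
    weight order.  When both endpoints are new, the one with larger rho
    (the larger underlying cluster) enters first; all remaining ties break
    on the smaller vertex index."""
    vs = sorted(raw_cluster)
    if len(vs) == 1:
        return list(vs)
    edges = sorted(
        ((u, v) for ai, u in enumerate(vs) for v in vs[ai + 1:]),
        key=lambda e: (-graph.W[e[0], e[1]], e[0], e[1]),
    )
    J: list[int] = []
    in_J: set[int] = set()
    for u, v in edges:
        if u in in_J and v in in_J:
            continue
        if u not in in_J and v not in in_J:
            first, second = (u, v) if graph.rho[u] >= graph.rho[v] else (v, u)
            J.extend((first, second))
            in_J.update((first, second))
        else:
            w = v if u in in_J else u
            J.append(w)
            in_J.add(w)
        if len(J) == len(vs):
            break
    return J


def intra_bin_weight(B: Sequence[int], graph: ClusterGraph) -> float:
    """``I_bin``: vertex weight for a one-vertex bin, otherwise the
    rho-weighted mean over all primitive pairs inside the bin."""
    B = list(B)
    if not B:
        raise ValueError("empty bin")
    if len(B) == 1:
        return float(graph.W[B[0], B[0]])
    num = 0.0
    den = 0.0
    for ai, u in enumerate(B):
        ru = float(graph.rho[u])
        pairs_u = ru * (ru - 1.0) / 2.0
        num += pairs_u * graph.W[u, u]
        den += pairs_u
        for v in B[ai + 1:]:
            rv = float(graph.rho[v])
            num += ru * rv * graph.W[u, v]
            den += ru * rv
    return num / den


def attach_weight(B: Sequence[int], v_t: int, graph: ClusterGraph) -> float:
    """``I``: rho-weighted mean edge weight between ``v_t`` and the bin."""
    if v_t in B:
        raise ValueError("candidate vertex already in bin")
    num = sum(float(graph.rho[u]) * graph.W[u, v_t] for u in B)
    den = sum(float(graph.rho[u]) for u in B)
    return num / den


def bin_score(B: Sequence[int], v_t: int, graph: ClusterGraph, gamma_low: float) -> float:
    """``Q = 2 * I - I_bin - gamma_low``; eligibility requires Q > 0."""
    return 2.0 * attach_weight(B, v_t, graph) - intra_bin_weight(B, graph) - gamma_low


def bin_raw_cluster(raw_cluster: Sequence[int], graph: ClusterGraph, gamma_low: float) -> list[list[int]]:
    """Split one raw cluster into bins, returned in creation order.

    The first vertex of J seeds bin 1; each later vertex joins the bin
    with the highest strictly positive score (earliest-created bin on a
    tie) or seeds a new bin.
    """
    J = order_vertices(raw_cluster, graph)
    bins: list[list[int]] = [[J[0]]]
    for v_t in J[1:]:
        best_idx = -1
        best_q = 0.0
        for bi, B in enumerate(bins):
            q = bin_score(B, v_t, graph, gamma_low)
            if q > best_q + _TIE_TOL:
                best_q, best_idx = q, bi
        if best_idx >= 0:
            bins[best_idx].append(v_t)
        else:
            bins.append([v_t])
    return bins
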