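"""External and internal cluster-validation indices.

NMI and purity compare a clustering against known classes; the silhouette
coefficient measures separation on a true (alignment-based) distance
matrix.  All three follow the standard information-theoretic / geometric
definitions; NMI uses natural logs (it is log-base invariant) and the
degenerate case of a single cluster and a single class is defined as 1.
"""

from __future__ import annotations

from math import log
from typing import Sequence

import numpy as np


def _check_partitions(L: Sequence[set], Omega: Sequence[set]) -> int:
    ids_L = [x for c in L for x in c]
    ids_O = [x for w in Omega for x in w]
    if len(ids_L) != len(set(ids_L)) or len(ids_O) != len(set(ids_O)):
        raise ValueError("clusters/classes must be disjoint")
    if set(ids_L) != set(ids_O):
        raise ValueError("clusters and classes must cover the same ids")
    return len(ids_L)


def nmi(L: Sequence[set], Omega: Sequence[set]) -> float:
    """Normalized mutual information 2*I(L;Omega) / (H(L) + H(Omega))."""
    N = _check_partitions(L, Omega)
    if N == 0:
        raise ValueError("empty clustering")
    H_L = -sum(len(c) / N * log(len(c) / N) for c in L if c)
    H_O = -sum(len(w) / N * log(len(w) / N) for w in Omega if w)
    if H_L + H_O == 0.0:
        return 1.0
    mi = 0.0
    for c in L:
        for w in Omega:
            inter = len(c & w)
            if inter:
                mi += inter / N * log(N * inter / (len(c) * len(w)))
    return 2.0 * mi / (H_L + H_O)


def purity(L: Sequence[set], Omega: Sequence[set]) -> float:
    """Fraction of sequences falling in their cluster's dominant class."""
    N = _check_partitions(L, Omega)
    return sum(max(len(c & w) for w in Omega) for c in L) / N


def silhouette(distances: np.ndarray, clustering: Sequence[Sequence[int]]) -> float:
    """Mean silhouette over all points of a clustering of >= 2 clusters.

    ``distances`` is a symmetric matrix with zero diagonal; clusters are
    index sets into it.  Members of singleton clusters contribute 0.
    """
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-9) or not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    clusters = [np.asarray(sorted(c), dtype=np.int64) for c in clustering]
    if len(clusters) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    covered = np.concatenate(clusters)
    if covered.size != D.shape[0] or len(np.unique(covered)) != D.shape[0]:
        raise ValueError("clusters must partition the point set")

    total = 0.0
    for ci, c in enumerate(clusters):
        for s in c:
            if c.size == 1:
                continue  # singleton contributes 0
            d_intra = (D[s, c].sum()) / (c.size - 1)
            d_neighbor = min(D[s, other].mean() for oj, other in enumerate(clusters) if oj != ci)
            denom = max(d_neighbor, d_intra)
            if denom > 0:
                total += (d_neighbor - d_intra) / denom
    return total / D.shape[0]
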