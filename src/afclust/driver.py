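"""The iterative clustering loop and the optional pre-clustering stage.

Starting from the full similarity graph, the resolution ``gamma`` descends
from ``gamma_high`` (default 0.95) to ``gamma_low`` (default 0.75) in exact
decimal steps of ``delta`` (default 0.025).  Each iteration detects raw
clusters by CPM maximization at the current gamma; on the first iteration
the raw clusters become validated clusters directly, afterwards every raw
cluster is split by the adaptive binning rule.  The graph is then
contracted so each validated cluster becomes one vertex, with sibling bins
from the same raw cluster barred from ever co-clustering.  The clusters of
the final iteration, expanded to primitive sequence ids, are the output.

Inputs larger than ``precluster_limit`` (default 20000 sequences) are
first divided into partitions by a greedy sketch-based pre-clusterer at
similarity threshold ``gamma_low``; each partition is clustered
independently, which leaves the result unchanged when cross-partition
similarities sit below ``gamma_low``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np

from .binning import bin_raw_cluster
from .community import detect_raw_clusters
from .graph import contract, init_graph
from .io import SequenceRecord
from .sketching import Sketch, SketchParams, build_sketch, build_similarity_matrix, mash_distance

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoreParams:
    """Resolution schedule and scalability knobs.

    gamma_high should stay near the maximum edge weight (>= 0.95
    recommended) so first-iteration raw clusters resist size bias;
    gamma_low is the soft cut-off every bin's adaptive threshold
    references (suggested range 0.7-0.8); delta should not exceed 0.025.
    """

    gamma_high: float = 0.95
    gamma_low: float = 0.75
    delta: float = 0.025
    precluster_limit: int = 20000
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.gamma_low < self.gamma_high <= 1.0:
            raise ValueError("need 0 < gamma_low < gamma_high <= 1")
        if self.delta <= 0:
            raise ValueError("delta must be positive")


@dataclass
class ClusterResult:
    """Final clusters as sets of primitive sequence ids."""

    clusters: list[set[str]]
    history: list[list[set[str]]] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def labels(self) -> dict[str, int]:
        return {sid: i for i, members in enumerate(self.clusters) for sid in members}


def _gamma_schedule(core: CoreParams) -> list[Fraction]:
    """Exact decimal gamma grid: gamma_high - i * delta while
    gamma > gamma_low - delta (binary floats would corrupt the bound)."""
    gh = Fraction(str(core.gamma_high))
    gl = Fraction(str(core.gamma_low))
    d = Fraction(str(core.delta))
    out: list[Fraction] = []
    g = gh
    while g > gl - d:
        out.append(g)
        g -= d
    return out


def _cluster_partition(
    seqs: Sequence[SequenceRecord],
    sketch_params: SketchParams,
    core: CoreParams,
    sketches: Optional[list[Sketch]] = None,
    keep_history: bool = False,
) -> ClusterResult:
    if len(seqs) == 1:
        return ClusterResult([{seqs[0].id}])
    ids = [s.id for s in seqs]
    W0 = build_similarity_matrix(seqs, sketch_params, sketches=sketches)
    graph = init_graph(W0)
    gamma_low = core.gamma_low
    history: list[list[set[str]]] = []

    for it, g in enumerate(_gamma_schedule(core)):
        gamma = float(g)
        partition = detect_raw_clusters(graph, gamma, rng_seed=core.seed)
        raw_clusters = partition.clusters
        if it == 0:
            L = raw_clusters
            siblings: list[list[int]] = []
        else:
            L = []
            siblings = []
            for rc in raw_clusters:
                bins = bin_raw_cluster(rc, graph, gamma_low) if len(rc) > 1 else [list(rc)]
                start = len(L)
                L.extend(bins)
                if len(bins) > 1:
                    siblings.append(list(range(start, len(L))))
        graph = contract(graph, L, siblings)
        if keep_history:
            history.append([{ids[p] for p in mem} for mem in graph.members])

    clusters = [{ids[p] for p in mem} for mem in graph.members]
    return ClusterResult(clusters, history)


def precluster(
    seqs: Sequence[SequenceRecord],
    sketch_params: SketchParams,
    gamma_low: float,
    sketches: Optional[list[Sketch]] = None,
) -> list[list[int]]:
    """Greedy sketch-based pre-clustering into sequence partitions.

    A sequence joins the first partition whose representative (its first
    sequence) has similarity >= gamma_low, else opens a new partition;
    partitions whose representatives meet the threshold are then merged by
    single linkage.  Cross-partition similarity therefore sits below
    gamma_low, so partitions can be clustered independently.  Returns
    partitions as lists of input indices.
    """
    if sketches is None:
        sketches = [build_sketch(s, sketch_params) for s in seqs]
    parts: list[list[int]] = []
    reps: list[int] = []
    for i in range(len(seqs)):
        placed = False
        for pi, rep in enumerate(reps):
            if 1.0 - mash_distance(sketches[i], sketches[rep]) >= gamma_low:
                parts[pi].append(i)
                placed = True
                break
        if not placed:
            parts.append([i])
            reps.append(i)

    # single-linkage union of partitions whose representatives meet the
    # threshold (a sequence may be near two representatives that are
    # themselves near each other only transitively)
    parent = list(range(len(parts)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a in range(len(reps)):
        for b in range(a + 1, len(reps)):
            if 1.0 - mash_distance(sketches[reps[a]], sketches[reps[b]]) >= gamma_low:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)

    merged: dict[int, list[int]] = {}
    for pi, members in enumerate(parts):
        merged.setdefault(find(pi), []).extend(members)
    return [sorted(merged[k]) for k in sorted(merged)]


def alfat_cluster(
    seqs: Sequence[SequenceRecord],
    sketch_params: Optional[SketchParams] = None,
    core_params: Optional[CoreParams] = None,
    force_precluster: bool = False,
    keep_history: bool = False,
) -> ClusterResult:
    """Cluster a sequence set with the adaptive-threshold algorithm.

    Sequences shorter than the k-mer size are dropped with a warning.
    A single surviving sequence yields one singleton cluster without
    building a graph.
    """
    core = core_params or CoreParams()
    if not seqs:
        raise ValueError("no input sequences")
    if sketch_params is None:
        sketch_params = SketchParams.for_alphabet(seqs[0].alphabet)

    usable = []
    for s in seqs:
        if len(s) < sketch_params.k:
            logger.warning("sequence %r shorter than k=%d; excluded", s.id, sketch_params.k)
        else:
            usable.append(s)
    if not usable:
        raise ValueError("no sequences left after length filtering")
    if len(usable) == 1:
        return ClusterResult([{usable[0].id}])

    if force_precluster or len(usable) > core.precluster_limit:
        sketches = [build_sketch(s, sketch_params) for s in usable]
        partitions = precluster(usable, sketch_params, core.gamma_low, sketches=sketches)
        logger.info("pre-clustering produced %d partitions", len(partitions))
        clusters: list[set[str]] = []
        for part in partitions:
            sub = [usable[i] for i in part]
            sub_sk = [sketches[i] for i in part]
            res = _cluster_partition(sub, sketch_params, core, sketches=sub_sk)
            clusters.extend(res.clusters)
        return ClusterResult(clusters)

    return _cluster_partition(usable, sketch_params, core, keep_history=keep_history)
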