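"""Cluster evaluation: representative centers and alignment identity.

For each non-singleton cluster a representative center is picked — the
member with the largest sum of intra-cluster similarities among members
whose length lies within the Tukey fences [Q1 - 1.5*IQR, Q3 + 1.5*IQR];
when no member qualifies or the cluster has only two members, the longest
sequence is taken.  Pairwise identity between the center and every other
member is then computed from a global alignment with free end gaps as
matched columns / alignment columns after trimming terminal-gap runs, so
the scoring scheme only influences the alignment path, not the identity
definition.

Alignment scoring: +1/-1 match/mismatch with gap -2 for nucleotides;
BLOSUM62 with gap open 11 / extend 1 for proteins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .io import NUCLEOTIDE, SequenceRecord


@dataclass(frozen=True)
class EvalRecord:
    cluster_index: int
    center_id: str
    size: int
    mean_identity: float
    min_identity: float
    min_identity_partner_id: str


def _make_aligner(alphabet: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if alphabet == NUCLEOTIDE:
        aligner.match_score = 1.0
        aligner.mismatch_score = -1.0
        aligner.open_gap_score = -2.0
        aligner.extend_gap_score = -2.0
    else:
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11.0
        aligner.extend_gap_score = -1.0
    # end gaps free: semi-global alignment
    if hasattr(aligner, "open_end_insertion_score"):
        aligner.open_end_insertion_score = 0.0
        aligner.extend_end_insertion_score = 0.0
        aligner.open_end_deletion_score = 0.0
        aligner.extend_end_deletion_score = 0.0
    else:  # Biopython < 1.86 attribute names
        aligner.target_end_open_gap_score = 0.0
        aligner.target_end_extend_gap_score = 0.0
        aligner.query_end_open_gap_score = 0.0
        aligner.query_end_extend_gap_score = 0.0
    return aligner


def pairwise_identity(a: SequenceRecord, b: SequenceRecord) -> float:
    """Matched columns / alignment length excluding terminal gaps."""
    if a.alphabet != b.alphabet:
        raise ValueError("sequences have different alphabets")
    if not a.residues or not b.residues:
        raise ValueError("empty sequence")
    if a.residues == b.residues:
        return 1.0
    aligner = _make_aligner(a.alphabet)
    aln = aligner.align(a.residues, b.residues)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    # trim columns inside a terminal-gap run of either sequence
    start = max(_first_residue(row_a), _first_residue(row_b))
    end = min(_last_residue(row_a), _last_residue(row_b)) + 1
    if end <= start:
        return 0.0
    matches = sum(1 for x, y in zip(row_a[start:end], row_b[start:end]) if x == y and x != "-")
    return matches / (end - start)


def _first_residue(row: str) -> int:
    return len(row) - len(row.lstrip("-"))


def _last_residue(row: str) -> int:
    return len(row.rstrip("-")) - 1


def select_center(
    cluster: Sequence[str],
    seqs: Mapping[str, SequenceRecord],
    W: np.ndarray,
    index: Mapping[str, int],
) -> str:
    """Representative center of a non-singleton cluster.

    ``W`` is a similarity matrix over (at least) the cluster members and
    ``index`` maps member ids into it.
    """
    members = sorted(cluster)
    if len(members) < 2:
        raise ValueError("center selection needs a non-singleton cluster")
    if len(members) == 2:
        return max(members, key=lambda m: (len(seqs[m]), _neg_ord(m)))
    lengths = np.array([len(seqs[m]) for m in members], dtype=float)
    q1, q3 = np.percentile(lengths, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    in_range = [m for m, L in zip(members, lengths) if lo <= L <= hi]
    if not in_range:
        return max(members, key=lambda m: (len(seqs[m]), _neg_ord(m)))
    idx = {m: index[m] for m in members}

    def weight_sum(m: str) -> float:
        return float(sum(W[idx[m], idx[o]] for o in members if o != m))

    best = in_range[0]
    best_sum = weight_sum(best)
    for m in in_range[1:]:
        ws = weight_sum(m)
        if ws > best_sum + 1e-12:
            best, best_sum = m, ws
    return best


class _neg_ord(str):
    """Reverses lexicographic comparison so max() breaks ties on the
    smallest id."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)


def evaluate_clusters(
    clusters: Sequence[set],
    seqs: Mapping[str, SequenceRecord],
    W: np.ndarray,
    index: Mapping[str, int],
) -> list[EvalRecord]:
    """Per-cluster report for every non-singleton cluster.

    Cluster indices follow the output-table ordering (descending size,
    ties by smallest member id); singletons are skipped.
    """
    ordered = sorted((sorted(c) for c in clusters), key=lambda m: (-len(m), m[0]))
    records: list[EvalRecord] = []
    for ci, members in enumerate(ordered):
        if len(members) < 2:
            continue
        center = select_center(members, seqs, W, index)
        others = [m for m in members if m != center]
        idents = [(pairwise_identity(seqs[center], seqs[o]), o) for o in others]
        min_ident, min_partner = min(idents, key=lambda t: (t[0], t[1]))
        records.append(
            EvalRecord(
                cluster_index=ci,
                center_id=center,
                size=len(members),
                mean_identity=float(np.mean([i for i, _ in idents])),
                min_identity=float(min_ident),
                min_identity_partner_id=min_partner,
            )
        )
    return records


def write_evaluation_csv(records: Sequence[EvalRecord], path) -> None:
    import pandas as pd

    df = pd.DataFrame(
        [
            (r.cluster_index, r.center_id, r.size, r.mean_identity, r.min_identity, r.min_identity_partner_id)
            for r in records
        ],
        columns=["cluster_index", "center_id", "size", "mean_identity", "min_identity", "min_identity_partner"],
    )
    df.to_csv(path, index=False)
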