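"""FASTA input and cluster-table / report output.

Sequences are modelled as :class:`SequenceRecord`; the alphabet of a
dataset (nucleotide vs protein) is auto-detected from residue composition
unless forced.  Cluster output is a plain TSV, one row per sequence.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

logger = logging.getLogger(__name__)

NUCLEOTIDE = "nucleotide"
PROTEIN = "protein"

_NT_CHARS = frozenset("ACGTUN")


class DuplicateIdError(ValueError):
    """Two records in one dataset share the same id."""


@dataclass(frozen=True)
class SequenceRecord:
    """One input sequence: unique ``id``, free-text ``description``,
    upper-cased ``residues`` and the dataset ``alphabet``."""

    id: str
    description: str
    residues: str
    alphabet: str

    def __len__(self) -> int:
        return len(self.residues)


def _detect_alphabet(residues_sample: str) -> str:
    """A dataset is called nucleotide when >=90% of sampled residues are
    in {A,C,G,T,U,N}."""
    if not residues_sample:
        return NUCLEOTIDE
    n_nt = sum(1 for c in residues_sample if c in _NT_CHARS)
    return NUCLEOTIDE if n_nt >= 0.9 * len(residues_sample) else PROTEIN


def read_fasta(
    path,
    alphabet: Optional[str] = None,
    min_length: int = 1,
) -> list[SequenceRecord]:
    """Read a (optionally gzipped) multi-FASTA file.

    Parameters
    ----------
    path:
        FASTA file path.
    alphabet:
        ``"nucleotide"`` / ``"protein"`` to force; ``None`` auto-detects
        for the whole dataset.
    min_length:
        Records shorter than this (typically the k-mer size) are excluded
        with a warning rather than aborting the run.

    Raises
    ------
    DuplicateIdError
        If two records share an id.
    ValueError
        If the file contains no records, or none survive the length filter.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        raw = [(r.id, r.description, str(r.seq).upper()) for r in SeqIO.parse(handle, "fasta")]
    if not raw:
        raise ValueError(f"no FASTA records found in {path}")

    seen: set[str] = set()
    for rid, _, _ in raw:
        if rid in seen:
            raise DuplicateIdError(f"duplicate sequence id {rid!r} in {path}")
        seen.add(rid)

    if alphabet is None:
        sample = "".join(res[:1000] for _, _, res in raw[:200])
        alphabet = _detect_alphabet(sample)
    if alphabet not in (NUCLEOTIDE, PROTEIN):
        raise ValueError(f"unknown alphabet {alphabet!r}")

    records: list[SequenceRecord] = []
    for rid, desc, res in raw:
        if alphabet == NUCLEOTIDE:
            res = res.replace("U", "T")
        if len(res) < min_length:
            logger.warning(
                "sequence %r (length %d) shorter than minimum %d; excluded",
                rid, len(res), min_length,
            )
            continue
        records.append(SequenceRecord(rid, desc, res, alphabet))
    if not records:
        raise ValueError(f"no usable records in {path} after length filter (min {min_length})")
    return records


def _ordered_clusters(clusters: Iterable[frozenset | set], centers=None) -> list[list[str]]:
    """Descending size, ties by lexicographically smallest member id."""
    return sorted((sorted(c) for c in clusters), key=lambda m: (-len(m), m[0]))


def write_cluster_table(clusters: Iterable[set], path, centers: Optional[dict] = None) -> None:
    """Write a TSV cluster table: ``cluster_index  sequence_id  is_center``.

    Cluster indices are 0-based, ordered by descending cluster size then by
    smallest member id.  ``centers`` maps a frozen member set to its center
    id; absent entries default to the smallest member id.
    """
    ordered = _ordered_clusters(clusters)
    if not ordered:
        raise ValueError("empty clustering")
    centers = centers or {}
    with open(path, "w") as fh:
        fh.write("cluster_index\tsequence_id\tis_center\n")
        for idx, members in enumerate(ordered):
            center = centers.get(frozenset(members), members[0])
            for sid in members:
                fh.write(f"{idx}\t{sid}\t{1 if sid == center else 0}\n")


def read_cluster_table(path) -> list[set[str]]:
    """Re-read a TSV written by :func:`write_cluster_table`."""
    by_index: dict[int, set[str]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("cluster_index"):
            raise ValueError(f"{path} is not a cluster table")
        for line in fh:
            idx_s, sid, _ = line.rstrip("\n").split("\t")
            by_index.setdefault(int(idx_s), set()).add(sid)
    return [by_index[i] for i in sorted(by_index)]


def write_representatives_fasta(records: list[SequenceRecord], rep_ids: Iterable[str], path) -> None:
    """Write the representative (center) sequences of each cluster."""
    by_id = {r.id: r for r in records}
    with open(path, "w") as fh:
        for rid in rep_ids:
            rec = by_id[rid]
            header = f">{rec.id} {rec.description}" if rec.description and rec.description != rec.id else f">{rec.id}"
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), 70):
                fh.write(rec.residues[i : i + 70] + "\n")
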