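"""Synthetic homologous-family generator for tests and demos.

Each family descends from an independent random ancestor.
``within_divergence`` is calibrated to the *pairwise* divergence between
family members: each member substitutes i.i.d. per site at
``within_divergence / 2`` relative to the ancestor (uniform over the
alternative residues), so the expected identity between two members is
about ``1 - within_divergence``.  Indel events occur per member at
``indel_rate`` per site with geometric lengths (mean 2, insertion or
deletion with equal probability).  Cross-family similarity is at random
background.  Ids encode the family, so generated datasets come with exact
ground-truth labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io import NUCLEOTIDE, PROTEIN, SequenceRecord

_NT = "ACGT"
_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class FamilySpec:
    """Generator conditions; defaults model complete-gene families with a
    wide within/between similarity gap."""

    n_families: int = 20
    seqs_per_family: tuple[int, int] = (5, 30)
    ancestor_length: tuple[int, int] = (600, 1200)
    within_divergence: float = 0.05
    indel_rate: float = 0.002
    alphabet: str = NUCLEOTIDE
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.within_divergence < 0.5:
            raise ValueError("within_divergence must be in [0, 0.5)")
        if self.alphabet not in (NUCLEOTIDE, PROTEIN):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        if self.indel_rate < 0:
            raise ValueError("indel_rate must be >= 0")


def _mutate(codes: np.ndarray, spec: FamilySpec, rng: np.random.Generator, n_letters: int) -> np.ndarray:
    out = codes.copy()
    # substitutions at half the pairwise divergence per member, uniform
    # over the alternative residues
    mask = rng.random(out.size) < spec.within_divergence / 2.0
    n_sub = int(mask.sum())
    if n_sub:
        out[mask] = (out[mask] + rng.integers(1, n_letters, size=n_sub)) % n_letters
    if spec.indel_rate > 0:
        events = np.flatnonzero(rng.random(out.size) < spec.indel_rate)
        pieces = []
        prev = 0
        for pos in events:
            length = int(rng.geometric(0.5))
            if rng.random() < 0.5:  # insertion after pos
                pieces.append(out[prev: pos + 1])
                pieces.append(rng.integers(0, n_letters, size=length).astype(out.dtype))
                prev = pos + 1
            else:  # deletion starting at pos
                pieces.append(out[prev:pos])
                prev = min(pos + length, out.size)
        pieces.append(out[prev:])
        out = np.concatenate(pieces) if pieces else out
    return out


def generate_families(spec: FamilySpec) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Generate labeled families; returns (records, id -> family label)."""
    rng = np.random.default_rng(spec.seed)
    letters = _NT if spec.alphabet == NUCLEOTIDE else _AA
    n_letters = len(letters)
    lut = np.frombuffer(letters.encode(), dtype=np.uint8)

    records: list[SequenceRecord] = []
    labels: dict[str, str] = {}
    for f in range(spec.n_families):
        fam = f"F{f:03d}"
        length = int(rng.integers(spec.ancestor_length[0], spec.ancestor_length[1] + 1))
        ancestor = rng.integers(0, n_letters, size=length).astype(np.uint8)
        n_members = int(rng.integers(spec.seqs_per_family[0], spec.seqs_per_family[1] + 1))
        for m in range(n_members):
            codes = _mutate(ancestor, spec, rng, n_letters)
            residues = lut[codes].tobytes().decode("ascii")
            sid = f"{fam}_M{m:03d}"
            records.append(SequenceRecord(sid, f"synthetic family {fam}", residues, spec.alphabet))
            labels[sid] = fam
    return records, labels


def write_labels_tsv(labels: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for sid in labels:
            fh.write(f"{sid}\t{labels[sid]}\n")


def read_labels_tsv(path) -> dict[str, str]:
    labels: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            sid, lab = line.split("\t")
            labels[sid] = lab
    return labels
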