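"""Bottom-s MinHash sketches and Mash-style pairwise distances.

A sequence's sketch is the ``s`` smallest distinct 64-bit hash values over
its valid k-mers (canonical form for nucleotides: a k-mer and its reverse
complement hash identically).  The Jaccard index ``j`` of two sequences is
estimated from the ``s`` smallest hashes of the merged sketches, and the
Mash distance is ``d = -ln(2j / (1 + j)) / k``, clamped to [0, 1].  The
similarity matrix used for graph clustering is ``W = 1 - D`` with unit
diagonal.

Hashing is an integer k-mer packing (2 bits per nucleotide, 5 bits per
amino acid) passed through the 64-bit MurmurHash3 finalizer with a fixed
seed, so sketches are reproducible across runs and platforms.  K-mers
containing ambiguous characters ('N', 'X', ...) are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io import NUCLEOTIDE, PROTEIN, SequenceRecord

DEFAULT_HASH_SEED = 42
DEFAULT_SKETCH_SIZE = 2000
DEFAULT_KMER_NT = 17
DEFAULT_KMER_NT_SHORT = 13
DEFAULT_KMER_AA = 9

_U64 = np.uint64

_NT_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    _NT_CODE[_c] = _i

_AA_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(b"ACDEFGHIKLMNPQRSTVWY"):
    _AA_CODE[_c] = _i


@dataclass(frozen=True)
class SketchParams:
    """MinHash parameters: k-mer size ``k``, sketch size ``s``, canonical
    (strand-insensitive) hashing for nucleotides, and the hash seed."""

    k: int = DEFAULT_KMER_NT
    s: int = DEFAULT_SKETCH_SIZE
    canonical: bool = True
    hash_seed: int = DEFAULT_HASH_SEED

    def __post_init__(self):
        if not 1 <= self.k <= 32:
            raise ValueError(f"k must be in [1, 32], got {self.k}")
        if self.s < 1:
            raise ValueError(f"sketch size must be >= 1, got {self.s}")

    @classmethod
    def for_alphabet(cls, alphabet: str, k: Optional[int] = None,
                     s: int = DEFAULT_SKETCH_SIZE, hash_seed: int = DEFAULT_HASH_SEED) -> "SketchParams":
        """Default parameters per alphabet: k=17 for nucleotides (13 is the
        recommended choice for short sequences, via ``k``), k=9 for proteins,
        sketch size 2000."""
        if alphabet == NUCLEOTIDE:
            return cls(k=k or DEFAULT_KMER_NT, s=s, canonical=True, hash_seed=hash_seed)
        if alphabet == PROTEIN:
            return cls(k=k or DEFAULT_KMER_AA, s=s, canonical=False, hash_seed=hash_seed)
        raise ValueError(f"unknown alphabet {alphabet!r}")


@dataclass(frozen=True)
class Sketch:
    """Bottom-s sketch: sorted distinct hash values (at most ``s``; fewer
    when the sequence has fewer distinct valid k-mers) plus the count of
    distinct valid k-mers and the parameters used."""

    hashes: np.ndarray
    n_kmers: int
    params: SketchParams = field(compare=False)


def _fmix64(x: np.ndarray, seed: int) -> np.ndarray:
    """MurmurHash3 64-bit finalizer, seed folded in up front."""
    h = x.astype(_U64, copy=True)
    h ^= _U64(seed & 0xFFFFFFFFFFFFFFFF)
    h ^= h >> _U64(33)
    h *= _U64(0xFF51AFD7ED558CCD)
    h ^= h >> _U64(33)
    h *= _U64(0xC4CEB9FE1A85EC53)
    h ^= h >> _U64(33)
    return h


def _pack_windows(codes: np.ndarray, k: int, base_bits: int) -> tuple[np.ndarray, np.ndarray]:
    """Big-endian packed integers for every length-k window, plus the
    validity mask (all window positions are unambiguous codes)."""
    n = codes.size - k + 1
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (win != 255).all(axis=1)
    shifts = (_U64(base_bits) * np.arange(k - 1, -1, -1, dtype=_U64))
    packed = (win.astype(_U64) << shifts).sum(axis=1, dtype=_U64)
    return packed, valid


def _fnv1a_windows(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """FNV-1a over raw codes for k-mers too long to pack (protein k > 12)."""
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (win != 255).all(axis=1)
    h = np.full(win.shape[0], 0xCBF29CE484222325, dtype=_U64)
    prime = _U64(0x100000001B3)
    for i in range(k):
        h = (h ^ win[:, i].astype(_U64)) * prime
    return h, valid


def _kmer_hashes(seq: SequenceRecord, params: SketchParams) -> np.ndarray:
    """Distinct hash values of all valid k-mers of ``seq``."""
    k = params.k
    data = np.frombuffer(seq.residues.encode("ascii"), dtype=np.uint8)
    if seq.alphabet == NUCLEOTIDE:
        codes = _NT_CODE[data]
        fwd, valid = _pack_windows(codes, k, 2)
        if params.canonical:
            # reverse complement of window i of the forward strand is
            # window n-k-i of the reverse-complemented sequence
            rc_codes = np.where(codes == 255, 255, 3 - codes)[::-1].copy()
            rev, _ = _pack_windows(rc_codes, k, 2)
            rev = rev[::-1]
            fwd = np.minimum(fwd, rev)
    else:
        codes = _AA_CODE[data]
        if k <= 12:
            fwd, valid = _pack_windows(codes, k, 5)
        else:
            fwd, valid = _fnv1a_windows(codes, k)
    kmers = np.unique(fwd[valid])
    return _fmix64(kmers, params.hash_seed)


def build_sketch(seq: SequenceRecord, params: SketchParams) -> Sketch:
    """Bottom-s sketch of one sequence.

    Raises ``ValueError`` if the sequence is shorter than ``k`` (callers
    are expected to filter such records up front).
    """
    if len(seq) < params.k:
        raise ValueError(
            f"sequence {seq.id!r} (length {len(seq)}) shorter than k={params.k}"
        )
    hashes = np.sort(np.unique(_kmer_hashes(seq, params)))
    n_kmers = int(hashes.size)
    return Sketch(hashes=hashes[: params.s], n_kmers=n_kmers, params=params)


def jaccard_estimate(a: Sketch, b: Sketch) -> float:
    """Mash's bottom-s union estimator of the k-mer Jaccard index.

    The ``s`` smallest hashes of the merged sketches are taken; ``j`` is
    the fraction of them present in both sketches.  When both sequences
    have at most ``s`` distinct k-mers this equals the exact Jaccard index.
    """
    if a.params != b.params:
        raise ValueError("sketches built with different parameters")
    s = a.params.s
    merged = np.union1d(a.hashes, b.hashes)[:s]
    if merged.size == 0:
        return 0.0
    shared = np.isin(merged, a.hashes, assume_unique=True) & np.isin(
        merged, b.hashes, assume_unique=True
    )
    return float(shared.sum()) / float(merged.size)


def mash_distance(a: Sketch, b: Sketch, params: Optional[SketchParams] = None) -> float:
    """Mash distance ``-ln(2j/(1+j))/k`` clamped to [0, 1]; ``j = 0`` gives 1."""
    if params is not None and (params != a.params or params != b.params):
        raise ValueError("sketch parameters do not match the supplied params")
    j = jaccard_estimate(a, b)
    if j <= 0.0:
        return 1.0
    if j >= 1.0:
        return 0.0
    k = a.params.k
    d = -np.log(2.0 * j / (1.0 + j)) / k
    return float(min(max(d, 0.0), 1.0))


def build_similarity_matrix(
    seqs: Sequence[SequenceRecord],
    params: SketchParams,
    sketches: Optional[list[Sketch]] = None,
) -> np.ndarray:
    """Similarity matrix ``W = 1 - D`` over a sequence set.

    Off-diagonal entries are ``1 - mash_distance``; the diagonal is 1
    (vertex weights of the initial graph, every vertex being a singleton
    cluster).  Symmetric by construction.
    """
    n = len(seqs)
    if n < 2:
        raise ValueError("need at least 2 sequences for a similarity matrix")
    if sketches is None:
        sketches = [build_sketch(s, params) for s in seqs]

    # shared-hash counts for all pairs at once via a sparse incidence
    # matrix; pairs whose merged sketch is truncated at s fall back to the
    # per-pair bottom-s merge
    from scipy import sparse

    all_hashes = np.concatenate([sk.hashes for sk in sketches])
    uniq, inv = np.unique(all_hashes, return_inverse=True)
    sizes = np.array([sk.hashes.size for sk in sketches])
    rows = np.repeat(np.arange(n), sizes)
    A = sparse.csr_matrix(
        (np.ones(inv.size, dtype=np.int64), (rows, inv)), shape=(n, uniq.size)
    )
    inter = (A @ A.T).toarray()

    k = params.k
    W = np.eye(n)
    for i in range(n):
        for jdx in range(i + 1, n):
            c = inter[i, jdx]
            union = sizes[i] + sizes[jdx] - c
            if c == 0:
                j = 0.0
            elif union <= params.s:
                j = c / union
            else:
                j = jaccard_estimate(sketches[i], sketches[jdx])
            if j <= 0.0:
                d = 1.0
            elif j >= 1.0:
                d = 0.0
            else:
                d = min(max(-np.log(2.0 * j / (1.0 + j)) / k, 0.0), 1.0)
            W[i, jdx] = W[jdx, i] = 1.0 - d
    return W
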