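"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from afclust.io import NUCLEOTIDE, SequenceRecord


# ---------------------------------------------------------------- oracles

def set_partitions(items: list):
    """Enumerate all set partitions of ``items`` (Bell-number many)."""
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def brute_force_cpm_optimum(W: np.ndarray, gamma: float) -> float:
    """Global CPM optimum by enumeration of all set partitions."""
    n = W.shape[0]
    best = -np.inf
    for part in set_partitions(list(range(n))):
        q = 0.0
        for block in part:
            for ai, u in enumerate(block):
                for v in block[ai + 1:]:
                    q += W[u, v] - gamma
        best = max(best, q)
    return best


def canonical_kmers(seq: str, k: int) -> set[str]:
    """Brute-force distinct canonical k-mers of a nucleotide string."""
    comp = str.maketrans("ACGT", "TGCA")
    out = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if any(c not in "ACGT" for c in kmer):
            continue
        rc = kmer.translate(comp)[::-1]
        out.add(min(kmer, rc))
    return out


def nw_free_endgap_score(a: str, b: str, match=1.0, mismatch=-1.0, gap=-2.0) -> float:
    """Independent dynamic-programming score of a global alignment with
    free end gaps (linear gap penalty)."""
    n, m = len(a), len(b)
    prev = np.zeros(m + 1)  # first row: free leading gaps in a
    for i in range(1, n + 1):
        cur = np.empty(m + 1)
        cur[0] = 0.0  # free leading gaps in b
        for j in range(1, m + 1):
            diag = prev[j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            up = prev[j] + (gap if j < m else 0.0)  # last column: free end gap
            left = cur[j - 1] + (gap if i < n else 0.0)
            cur[j] = max(diag, up, left)
        prev = cur
    return float(prev[m])


def random_similarity(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random symmetric similarity matrix with unit diagonal."""
    M = rng.random((n, n))
    M = (M + M.T) / 2.0
    np.fill_diagonal(M, 1.0)
    return M


def nt_record(rid: str, residues: str) -> SequenceRecord:
    return SequenceRecord(rid, "", residues, NUCLEOTIDE)


def random_nt(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


# ---------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def family_dataset():
    """The reference synthetic dataset: 20 families, 5-30 members each,
    ancestors 600-1200 nt, 5% within-family divergence."""
    from afclust.simulate import FamilySpec, generate_families

    records, labels = generate_families(FamilySpec(seed=1))
    classes: dict[str, set] = {}
    for sid, lab in labels.items():
        classes.setdefault(lab, set()).add(sid)
    return records, labels, list(classes.values())


@pytest.fixture(scope="session")
def worked_example_graph():
    """The five-vertex graph of the size-bias illustration: w12 = 0.89,
    {w13, w14, w15, w34, w35, w45} = {0.84, 0.86, 0.87, 0.85, 0.87, 0.86};
    remaining pairs are weakly connected."""
    from afclust.graph import init_graph

    W = np.full((5, 5), 0.5)
    np.fill_diagonal(W, 1.0)
    pairs = {(0, 1): 0.89, (0, 2): 0.84, (0, 3): 0.86, (0, 4): 0.87,
             (2, 3): 0.85, (2, 4): 0.87, (3, 4): 0.86}
    for (i, j), w in pairs.items():
        W[i, j] = W[j, i] = w
    return init_graph(W)
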