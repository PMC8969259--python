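# Methods

## Model and procedure

`afclust` treats sequence clustering as iterative community detection on a
complete weighted graph. Vertices start as single sequences; edge weights
are alignment-free similarity estimates `w_ij = 1 − d_ij`, where `d_ij` is
the Mash distance derived from bottom-`s` MinHash sketches. Writing `j`
for the Jaccard index of two k-mer sets estimated from the `s` smallest
hashes of the merged sketches,

    d = −ln(2j / (1 + j)) / k,   clamped to [0, 1];  j = 0 ⇒ d = 1.

The clamp enforces the working range of the similarity graph; for closely
related sequences `d` approximates per-site divergence, so `w` tracks
average nucleotide identity well in the regime that matters (w ≳ 0.7) and
degrades gracefully below it — the algorithm is designed so that weights
under `γ_low` never decide a merge.

Each iteration at resolution `γ` maximizes the Constant Potts Model
quality `q = Σ_{i<j} (w_ij − γ) δ(σ_i, σ_j)` over partitions. Because the
graph is complete and has no self-loops, vertex weights (diagonal entries)
never enter `q`; an all-singleton partition scores 0, so the optimum is
non-negative and every member of a non-singleton community has mean
intra-community edge weight above `γ`. Sweeping `γ` downward from near the
maximum edge weight and contracting after every iteration makes the
procedure behave like average-linkage agglomeration that processes the
most reliable (smallest) distances first, while the binning rule
(`Q = 2I − I_bin − γ_low > 0`, strict) stops any merge whose separation
exceeds its adaptive cut-off. ρ-weighted bin statistics make every vertex-
level average equal the corresponding mean over *primitive* sequence
pairs, which is also how contraction recomputes all weights (see below).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `k` | 17 nt / 9 aa (13 for short nt) | k-mer size of the sketch; smaller k for short sequences keeps enough shared k-mers |
| `s` | 2000 | sketch size; with ≤ `s` distinct k-mers per sequence the Jaccard estimate is exact |
| `γ_high` | 0.95 | start resolution; ≥ 0.95 keeps first-iteration communities robust against CPM's size bias |
| `γ_low` | 0.75 | soft cut-off referenced by every bin's adaptive threshold; suggested range 0.7–0.8 |
| `Δ` | 0.025 | resolution step; smaller steps reduce size bias per iteration, 0.025 is the recommended ceiling |
| `precluster_limit` | 20000 | input size beyond which greedy pre-clustering divides the work |
| `seed` | 0 | RNG seed for the Leiden partitioner |

`γ` values are generated on an exact decimal grid (`fractions.Fraction` of
the decimal strings), because the loop bound `γ > γ_low − Δ` is fragile
under binary floating point.

## Numerical and design choices

- **Hashing.** k-mers are packed into 64-bit integers (2 bits per
  nucleotide — the canonical strand is the lexicographic minimum of a
  window and its reverse complement — 5 bits per amino acid, an FNV-1a
  byte fallback for protein k > 12) and passed through the MurmurHash3
  64-bit finalizer with a fixed seed, so sketches are identical across
  runs and platforms. K-mers containing ambiguous characters are skipped
  rather than randomized.
- **Similarity matrix.** Pairwise shared-hash counts are computed for all
  pairs at once through a sparse incidence matrix; a pair falls back to
  the explicit bottom-`s` merge only when its merged sketch would be
  truncated (both routes are verified equal in the tests).
- **Partitioner.** leidenalg's CPM partitioner (seeded, iterated to
  stability) followed by a deterministic single-vertex local-move pass.
  The contract is: `q ≥ 0`, no single-vertex move can improve `q`, no
  forbidden pair co-clustered, and determinism under a fixed seed. Global
  optimality is not promised — the partitioner is a heuristic — but on
  random complete graphs with n ≤ 8 it matches exhaustive enumeration in
  well over 95% of instances.
- **Contraction.** New vertex and edge weights are recomputed directly
  from the initial primitive similarity matrix (means over primitive
  pairs), which is algebraically identical to the ρ-weighted averaging of
  the previous level but keeps the forbidden-pair sentinel (−|V|²) out of
  every average. Forbidden status is hereditary: the ledger is re-mapped
  and re-applied with the current −|V|² after each contraction, so sibling
  bins can never reunite in any later iteration. (The alternative —
  expiring the bar after one iteration — would let a bin split at
  resolution γ be undone at γ − Δ, defeating the purpose of binning.)
- **Tie-breaks** (all chosen for determinism): equal edge weights sort by
  the smaller vertex-index pair; equal ρ when both endpoints are new
  appends the smaller index first; equal maximal bin scores prefer the
  earliest-created bin; `Q = 0` exactly opens a new bin (the eligibility
  inequality is strict); center-selection ties prefer the smaller id.
- **Degenerate inputs.** A single sequence (or one survivor after length
  filtering) returns one singleton cluster without building a graph;
  sequences shorter than `k` are dropped with a warning naming them;
  duplicate ids and empty files abort.
- **Evaluation alignment.** Global alignment with free end gaps
  (+1/−1 match/mismatch, gap −2 for nucleotides; BLOSUM62 with gap open
  11 / extend 1 for proteins). Identity is matched columns divided by the
  alignment columns remaining after trimming terminal-gap runs of either
  sequence, so the scoring scheme influences only the alignment path, not
  the identity definition. These scores are a repository convention.
- **Quartiles** for the center-selection length fence use linear
  interpolation (`numpy.percentile` default).
- **Silhouette** assigns 0 to members of singleton clusters (the
  scikit-learn convention); NMI uses natural logarithms and defines the
  degenerate single-cluster/single-class case as 1.

## Synthetic data generator

`simulate.generate_families` emulates sets of homologous gene families:
one random ancestor per family (independent across families, so
between-family similarity is at random background), members derived by
i.i.d. substitutions and geometric indels. `within_divergence` is
calibrated to the *pairwise* divergence between members — each member
substitutes at `within_divergence / 2` relative to the ancestor — so the
measured member-to-member identity is ≈ `1 − within_divergence`. Defaults
(20 families, 5–30 members, ancestors 600–1200 nt, 5% within-family
divergence, indel rate 0.002/site with mean length 2 — an
indel:substitution event ratio of ≈ 1:12, typical of homologous coding
genes) model complete-gene datasets with a wide within/between similarity
gap.

What the generator does *not* model: partially overlapping sequences
(which are known to make Mash underestimate distance), domain shuffling,
compositional bias, codon structure, or families whose similarity to each
other approaches the within-family level. Passing the synthetic tests
therefore shows that the algorithm recovers well-separated families
robustly across `γ_low`; it does not certify behaviour on datasets where
family boundaries are genuinely ambiguous — there, the evaluation report
is the intended safeguard.

## Problem sizes used in tests

The test suite and reproduction script run at desk scale by design: the
reference synthetic dataset is 20 families / ~350 sequences, oracle
equivalences use exhaustive enumeration up to 8 vertices (set-partition
enumeration) and 30 primitives (contraction chains), and repeatability is
checked over 10 runs. The pre-clustering path is exercised by forcing it
on the reference dataset rather than by exceeding the 20 000-sequence
default limit.

## Known limitations

- Mash distance underestimates divergence for partially overlapping
  sequences; such pairs can be over-merged (inspect the evaluation
  report's minimum identities).
- The CPM partitioner is heuristic; pathological weight configurations
  can yield locally- but not globally-optimal raw clusters.
- Pre-clustering equivalence holds only when cross-partition similarity
  is genuinely below `γ_low`; the greedy representative choice is
  order-dependent at the margin.
- Not suitable for fixed-threshold OTU clustering at 97% identity.
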