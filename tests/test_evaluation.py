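import numpy as np
import pytest

from afclust.evaluation import evaluate_clusters, pairwise_identity, select_center
from afclust.io import PROTEIN, SequenceRecord

from conftest import nt_record, nw_free_endgap_score, random_nt


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        a = nt_record("a", "ACGTACGTAA")
        assert pairwise_identity(a, a) == 1.0

    def test_flush_right_overhang_is_trimmed(self):
        # "ACGT" aligns flush right inside "TTACGT"; the two leading gap
        # columns are terminal and excluded, leaving 4/4 matches
        a = nt_record("a", "ACGT")
        b = nt_record("b", "TTACGT")
        assert pairwise_identity(a, b) == 1.0
        assert pairwise_identity(b, a) == 1.0

    def test_single_substitution(self):
        a = nt_record("a", "ACGTACGTACGT")
        b = nt_record("b", "ACGTACTTACGT")
        assert pairwise_identity(a, b) == pytest.approx(11 / 12)

    def test_alignment_score_matches_dp_oracle(self):
        rng = np.random.default_rng(0)
        from afclust.evaluation import _make_aligner

        aligner = _make_aligner("nucleotide")
        for _ in range(5):
            s1, s2 = random_nt(rng, 60), random_nt(rng, 70)
            assert aligner.score(s1, s2) == pytest.approx(nw_free_endgap_score(s1, s2))

    def test_unrelated_below_related_and_symmetric(self):
        rng = np.random.default_rng(1)
        a = nt_record("a", random_nt(rng, 100))
        unrelated = nt_record("b", random_nt(rng, 100))
        related = list(a.residues)
        for pos in rng.integers(0, 100, size=5):
            related[pos] = "ACGT"[rng.integers(0, 4)]
        rel = nt_record("c", "".join(related))
        i_un = pairwise_identity(a, unrelated)
        assert 0.0 <= i_un <= 1.0
        assert i_un == pytest.approx(pairwise_identity(unrelated, a))
        assert pairwise_identity(a, rel) > i_un

    def test_protein_identity(self):
        a = SequenceRecord("a", "", "MKVLYWQHRDEIST", PROTEIN)
        b = SequenceRecord("b", "", "MKVLYWAHRDEIST", PROTEIN)
        assert pairwise_identity(a, b) == pytest.approx(13 / 14)

    def test_empty_or_mixed_alphabet_fatal(self):
        a = nt_record("a", "ACGT")
        p = SequenceRecord("p", "", "MKVL", PROTEIN)
        with pytest.raises(ValueError):
            pairwise_identity(a, p)


class TestSelectCenter:
    def _seqs(self, lengths):
        rng = np.random.default_rng(7)
        return {f"s{i}": nt_record(f"s{i}", random_nt(rng, L)) for i, L in enumerate(lengths)}

    def test_two_member_cluster_takes_longest(self):
        seqs = self._seqs([900, 1000])
        W = np.array([[1.0, 0.9], [0.9, 1.0]])
        idx = {"s0": 0, "s1": 1}
        assert select_center(["s0", "s1"], seqs, W, idx) == "s1"

    def test_all_identical_tie_broken_by_smallest_id(self):
        seqs = self._seqs([500, 500, 500])
        W = np.ones((3, 3))
        idx = {f"s{i}": i for i in range(3)}
        assert select_center(["s0", "s1", "s2"], seqs, W, idx) == "s0"

    def test_length_outlier_excluded_despite_max_weight_sum(self):
        # s4 is a length outlier with the largest similarity sum; the
        # center must come from the four in-range members
        seqs = self._seqs([1000, 1010, 990, 1005, 5000])
        W = np.full((5, 5), 0.8)
        np.fill_diagonal(W, 1.0)
        W[4, :] = W[:, 4] = 0.99
        W[1, :3] = W[:3, 1] = 0.9  # best in-range member: s1
        W[4, 4] = W[1, 1] = 1.0
        idx = {f"s{i}": i for i in range(5)}
        assert select_center([f"s{i}" for i in range(5)], seqs, W, idx) == "s1"

    def test_singleton_is_an_error(self):
        seqs = self._seqs([100])
        with pytest.raises(ValueError):
            select_center(["s0"], seqs, np.eye(1), {"s0": 0})


class TestEvaluateClusters:
    def test_identical_members_score_one(self):
        seq = random_nt(np.random.default_rng(3), 200)
        seqs = {f"s{i}": nt_record(f"s{i}", seq) for i in range(3)}
        W = np.ones((3, 3))
        idx = {f"s{i}": i for i in range(3)}
        (rec,) = evaluate_clusters([set(seqs)], seqs, W, idx)
        assert rec.mean_identity == rec.min_identity == 1.0
        assert rec.size == 3

    def test_singletons_absent_and_min_le_mean(self):
        rng = np.random.default_rng(4)
        base = random_nt(rng, 300)
        mutated = base[:100] + "".join(
            "ACGT"[rng.integers(0, 4)] for _ in range(20)
        ) + base[120:]
        seqs = {
            "a": nt_record("a", base),
            "b": nt_record("b", mutated),
            "c": nt_record("c", base[:250]),
            "lone": nt_record("lone", random_nt(rng, 300)),
        }
        W = np.full((4, 4), 0.9)
        np.fill_diagonal(W, 1.0)
        idx = {k: i for i, k in enumerate(["a", "b", "c", "lone"])}
        recs = evaluate_clusters([{"a", "b", "c"}, {"lone"}], seqs, W, idx)
        assert len(recs) == 1  # only the non-singleton cluster is reported
        assert recs[0].min_identity <= recs[0].mean_identity
        assert recs[0].min_identity_partner_id in {"a", "b", "c"}
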