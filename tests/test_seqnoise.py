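"""PCR transition model, homopolymer-aware alignment, and stage-two clustering."""

import math

import numpy as np
import pytest

from ampdenoise.align import align, unit_cost_matrix
from ampdenoise.seqnoise import (
    TransitionModel,
    WeightedSequence,
    align_homopolymer_nw,
    pairwise_distances,
    per_cycle_rate,
    run_seqnoise,
    seq_distance,
)

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def oracle_min_alignment_cost(a, b, sub, gap, hgap, use_hp=True):
    """Exhaustive minimum over all global alignments (column enumeration).

    Builds every monotone alignment path explicitly and scores its columns
    with the same flanking-base gap rule; independent of the DP recurrence.
    """

    def gap_cost(base, other, pos):
        if use_hp:
            if pos >= 1 and other[pos - 1] == base:
                return hgap
            if pos < len(other) and other[pos] == base:
                return hgap
        return gap

    best = [math.inf]

    def rec(i, j, cost):
        if cost >= best[0]:
            return
        if i == len(a) and j == len(b):
            best[0] = cost
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, cost + sub[_CODE[a[i]], _CODE[b[j]]])
        if i < len(a):
            rec(i + 1, j, cost + gap_cost(a[i], b, j))
        if j < len(b):
            rec(i, j + 1, cost + gap_cost(b[j], a, i))

    rec(0, 0, 0.0)
    return best[0]


class TestTransitionModel:
    def test_rows_are_proper_distributions(self, tm):
        probs = tm.probs()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(np.diag(probs) == probs.max(axis=1))

    def test_transitions_cheaper_than_transversions(self, tm):
        d = tm.sub_neg_log  # [true, observed], A C G T
        a, c, g, t = 0, 1, 2, 3
        assert d[a, g] < min(d[a, c], d[a, t])  # A->G transition
        assert d[g, a] < min(d[g, c], d[g, t])
        assert d[c, t] < min(d[c, a], d[c, g])
        assert d[t, c] < min(d[t, a], d[t, g])

    def test_per_cycle_rate_halves_the_cycle_count(self):
        # ideal doubling: a read's lineage is newly synthesised in c/2 cycles
        assert per_cycle_rate(4.2e-4, 30) == pytest.approx(2.8e-5, rel=1e-12)

    def test_tsv_roundtrip(self, tm, tmp_path):
        path = tmp_path / "trans.tsv"
        tm.save(path)
        back = TransitionModel.load(path)
        np.testing.assert_allclose(back.sub_neg_log, tm.sub_neg_log, rtol=1e-4)

    def test_invalid_penalties_rejected(self):
        with pytest.raises(ValueError):
            TransitionModel(np.zeros((4, 4)), gap_penalty=-1.0)


class TestAlignment:
    def test_identical_sequences_cost_is_diagonal_sum(self, tm):
        aln = align_homopolymer_nw("ACGT", "ACGT", tm)
        expected = sum(tm.sub_neg_log[_CODE[c], _CODE[c]] for c in "ACGT")
        assert aln.cost == pytest.approx(expected, rel=1e-12)
        assert "-" not in aln.a_aligned + aln.b_aligned

    def test_homopolymer_gap_is_cheap(self, tm):
        aln = align_homopolymer_nw("AAAT", "AAT", tm)
        match = sum(tm.sub_neg_log[_CODE[c], _CODE[c]] for c in "AAT")
        assert aln.cost == pytest.approx(4.0 + match, abs=1e-6)

    def test_standard_gap_when_not_flanked(self, tm):
        aln = align_homopolymer_nw("ACGT", "AGT", tm)
        match = sum(tm.sub_neg_log[_CODE[c], _CODE[c]] for c in "AGT")
        assert aln.cost == pytest.approx(15.0 + match, abs=1e-6)

    def test_column_costs_sum_to_total(self, tm):
        aln = align_homopolymer_nw("ACCGTTA", "ACGTA", tm)
        assert aln.column_costs.sum() == pytest.approx(aln.cost, rel=1e-12)

    def test_oracle_equivalence_short_sequences(self, tm):
        """DP optimum equals exhaustive enumeration for sequences <= 8 nt."""
        rng = np.random.default_rng(21)
        pairs = [
            ("AAAT", "AAT"),
            ("ACGT", "AGT"),
            ("TTTT", "T"),
            ("ACACAC", "CACACA"),
        ]
        for _ in range(12):
            la, lb = rng.integers(1, 7, size=2)
            pairs.append(
                (
                    "".join(rng.choice(list("ACGT"), la)),
                    "".join(rng.choice(list("ACGT"), lb)),
                )
            )
        pairs.append(("ACGTACGT", "AGGTACT"))  # one 8 nt case
        sub = tm.sub_neg_log.T
        for a, b in pairs:
            got = align_homopolymer_nw(a, b, tm).cost
            want = oracle_min_alignment_cost(
                a, b, sub, tm.gap_penalty, tm.homopolymer_gap_penalty
            )
            assert got == pytest.approx(want, rel=1e-10), (a, b)

    def test_unit_cost_alignment_counts_differences(self):
        aln = align("ACGTACGT", "ACGAACGT", sub=unit_cost_matrix(), gap=1.0,
                    homopolymer_aware=False)
        assert aln.cost == 1.0
        assert aln.differences() == 1


class TestSeqDistance:
    def test_identity_distance_from_diagonal(self, tm):
        e = seq_distance("A" * 100, "A" * 100, tm)
        assert e == pytest.approx(-math.log(0.9995), abs=5e-5)

    def test_single_transition_among_100(self, tm):
        read = "A" * 50 + "G" + "A" * 49
        true = "A" * 100
        e = seq_distance(read, true, tm)
        # 99 identity columns + one observed G over true A
        assert e == pytest.approx(0.076, abs=2e-3)

    def test_standard_gap_anchor(self):
        """One non-homopolymer gap per 100 columns contributes 0.15."""
        # zero-cost matches, prohibitive mismatches: isolates the gap term
        ident = TransitionModel(100.0 * (1.0 - np.eye(4)))
        a = "ACGT" * 25
        b = a[:50] + a[51:]  # drop one G; flanks C and T
        aln = align_homopolymer_nw(a, b, ident)
        assert aln.n_columns == 100
        assert seq_distance(a, b, ident) == pytest.approx(0.15, abs=1e-9)

    def test_first_argument_is_the_read(self, tm):
        # P(G|A) = 5.1e-4 but P(A|G) = 3.5e-4: asymmetric by design
        assert seq_distance("G", "A", tm) == pytest.approx(-math.log(5.1e-4), abs=2e-3)
        assert seq_distance("A", "G", tm) == pytest.approx(-math.log(3.5e-4), abs=2e-3)
        assert seq_distance("G", "A", tm) != seq_distance("A", "G", tm)

    def test_distance_nonnegative(self, tm):
        rng = np.random.default_rng(22)
        for _ in range(10):
            a = "".join(rng.choice(list("ACGT"), rng.integers(5, 30)))
            b = "".join(rng.choice(list("ACGT"), rng.integers(5, 30)))
            assert seq_distance(a, b, tm) >= 0.0


class TestRunSeqnoise:
    def test_single_sequence_identity(self, tm):
        seqs = [WeightedSequence("s1", "ACGTACGTAC", 7.0)]
        res = run_seqnoise(seqs, tm)
        assert len(res.sequences) == 1
        assert res.sequences[0].seq == "ACGTACGTAC"
        assert res.sequences[0].weight == 7.0

    def test_satellite_merges_into_abundant_sequence(self, tm):
        rng = np.random.default_rng(23)
        true = "".join(rng.choice(list("ACGT"), 100))
        sat = true[:40] + ("A" if true[40] != "A" else "C") + true[41:]
        seqs = [WeightedSequence("t", true, 100.0), WeightedSequence("s", sat, 2.0)]
        res = run_seqnoise(seqs, tm)
        assert len(res.sequences) == 1
        assert res.sequences[0].seq == true
        assert res.sequences[0].weight == 102.0
        assert res.mapping["s"] == res.mapping["t"]

    def test_divergent_sequences_both_retained(self, tm):
        rng = np.random.default_rng(24)
        a = "".join(rng.choice(list("ACGT"), 100))
        b = list(a)
        for pos in rng.choice(100, size=8, replace=False):  # 8% divergence
            b[pos] = "ACGT"[(_CODE[b[pos]] + 2) % 4]
        b = "".join(b)
        res = run_seqnoise(
            [WeightedSequence("a", a, 50.0), WeightedSequence("b", b, 50.0)], tm
        )
        assert {s.seq for s in res.sequences} == {a, b}

    def test_weight_conservation_exact(self, tm):
        rng = np.random.default_rng(25)
        base = "".join(rng.choice(list("ACGT"), 60))
        seqs = []
        for i in range(6):
            s = list(base)
            if i:
                s[i] = "ACGT"[(_CODE[s[i]] + 1) % 4]
            seqs.append(WeightedSequence(f"q{i}", "".join(s), float(rng.integers(1, 40))))
        res = run_seqnoise(seqs, tm)
        assert sum(s.weight for s in res.sequences) == sum(s.weight for s in seqs)

    def test_truncation_applied_before_clustering(self, tm):
        rng = np.random.default_rng(26)
        core = "".join(rng.choice(list("ACGT"), 220))
        tails = [core + "AAAA", core + "GGGG"]
        res = run_seqnoise(
            [WeightedSequence("a", tails[0], 3.0), WeightedSequence("b", tails[1], 2.0)],
            tm,
            truncate_len=220,
        )
        assert len(res.sequences) == 1
        assert res.sequences[0].seq == core

    def test_empty_input_raises(self, tm):
        with pytest.raises(ValueError):
            run_seqnoise([], tm)


def test_parallel_distance_matrix_is_bit_identical(tm):
    rng = np.random.default_rng(27)
    seqs = ["".join(rng.choice(list("ACGT"), 40)) for _ in range(6)]
    serial = pairwise_distances(seqs, seqs, tm, n_jobs=1)
    parallel = pairwise_distances(seqs, seqs, tm, n_jobs=2)
    np.testing.assert_array_equal(serial, parallel)
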