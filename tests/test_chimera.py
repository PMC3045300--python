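"""Chimera detection: parent search, parsimony counts, index, classification."""

import itertools
import math
import warnings

import numpy as np
import pytest

from ampdenoise.chimera import (
    LogisticModel,
    chimera_index,
    find_best_parents,
    logistic_predict,
    logistic_train,
    parsimony_change_counts,
    run_perseus,
)
from ampdenoise.seqnoise import WeightedSequence, align_homopolymer_nw


def rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def oracle_binomial_tail(k, n, p):
    """Pr[Bin(n, p) >= k] by exhaustive enumeration of all 2^n outcomes."""
    total = 0.0
    for bits in itertools.product([0, 1], repeat=n):
        c = sum(bits)
        if c >= k:
            total += p**c * (1 - p) ** (n - c)
    return total


def oracle_best_splice(query, parents, tm):
    """Explicit pair x breakpoint scan over prefix/suffix alignment costs."""
    from ampdenoise.align import prefix_costs

    fwd, rev = [], []
    for p in parents:
        fwd.append(
            prefix_costs(query, p.seq, tm.sub_neg_log.T, tm.gap_penalty,
                         tm.homopolymer_gap_penalty)
        )
        rev.append(
            prefix_costs(query[::-1], p.seq[::-1], tm.sub_neg_log.T, tm.gap_penalty,
                         tm.homopolymer_gap_penalty)[::-1]
        )
    best = None
    for bp in range(len(query) + 1):
        for li in range(len(parents)):
            for ri in range(len(parents)):
                c = fwd[li][bp] + rev[ri][bp]
                if best is None or c < best[0]:
                    best = (c, bp, li, ri)
    return best


class TestParsimony:
    def test_identical_rows_no_changes(self):
        assert parsimony_change_counts("ACGT", "ACGT", "ACGT", 2) == (0,) * 6

    def test_perfect_bimera_counts(self):
        rng = np.random.default_rng(31)
        a = list(rand_seq(rng, 40))
        b = a.copy()
        for pos in [1, 4, 7, 10, 13, 16]:  # 6 differences left of the break
            b[pos] = "ACGT"[("ACGT".index(b[pos]) + 1) % 4]
        for pos in [25, 30, 35, 38]:  # 4 differences right of the break
            b[pos] = "ACGT"[("ACGT".index(b[pos]) + 2) % 4]
        a, b = "".join(a), "".join(b)
        c = a[:20] + b[20:]
        x_a, x_b, y_a, y_b, z_a, z_b = parsimony_change_counts(a, b, c, 20)
        assert (y_a, y_b) == (6, 0)  # distant parent changes sit in A's part
        assert (x_a, x_b) == (0, 4)  # close parent changes sit in B's part
        assert (z_a, z_b) == (0, 0)

    def test_query_only_change_counts_on_its_side(self):
        a = "ACGTACGT"
        c = "ACGTACCT"  # column 6 differs only in the query
        assert parsimony_change_counts(a, a, c, 4) == (0, 0, 0, 0, 0, 1)
        assert parsimony_change_counts(a, a, c, 7) == (0, 0, 0, 0, 1, 0)

    def test_three_distinct_states_attribute_nothing(self):
        assert parsimony_change_counts("A", "C", "G", 1) == (0,) * 6


class TestChimeraIndex:
    def test_no_changes_zero_index(self):
        assert chimera_index((0, 0, 0, 0, 0, 0), 50, 50) == 0.0

    def test_fully_biased_equal_parts(self):
        # 6 distant-parent changes all in part A, 4 close ones all in part B
        got = chimera_index((0, 4, 6, 0, 0, 0), 100, 100)
        assert got == pytest.approx(10 * math.log(2), rel=1e-12)

    def test_partial_bias(self):
        got = chimera_index((0, 0, 2, 1, 0, 0), 80, 80)
        assert got == pytest.approx(-math.log(0.5), rel=1e-12)

    def test_matches_enumeration_oracle(self):
        """Binomial tails agree with exhaustive outcome enumeration (<= 12)."""
        rng = np.random.default_rng(32)
        for _ in range(25):
            y = int(rng.integers(0, 7))
            x = int(rng.integers(0, 6))
            y_a = int(rng.integers(0, y + 1))
            x_b = int(rng.integers(0, x + 1))
            len_a, len_b = int(rng.integers(10, 200)), int(rng.integers(10, 200))
            frac = len_a / (len_a + len_b)
            want = -math.log(
                oracle_binomial_tail(y_a, y, frac) * oracle_binomial_tail(x_b, x, 1 - frac)
            )
            got = chimera_index((x - x_b, x_b, y_a, y - y_a, 0, 0), len_a, len_b)
            assert got == pytest.approx(want, abs=1e-12)

    def test_monotone_in_biased_counts(self):
        prev = -1.0
        for y_a in range(7):
            got = chimera_index((0, 0, y_a, 6 - y_a, 0, 0), 90, 110)
            assert got >= prev - 1e-12
            prev = got
        prev = -1.0
        for x_b in range(6):
            got = chimera_index((5 - x_b, x_b, 0, 0, 0, 0), 90, 110)
            assert got >= prev - 1e-12
            prev = got

    def test_empty_parts_rejected(self):
        with pytest.raises(ValueError):
            chimera_index((0, 0, 0, 0, 0, 0), 0, 100)


class TestFindBestParents:
    def test_query_identical_to_candidate(self, tm):
        rng = np.random.default_rng(33)
        seq = rand_seq(rng, 60)
        query = WeightedSequence("q", seq, 1.0)
        pool = [WeightedSequence("p", seq, 10.0), WeightedSequence("o", rand_seq(rng, 60), 10.0)]
        a, b, bp, dc, dp = find_best_parents(query, pool, tm)
        assert dc == pytest.approx(dp, rel=1e-9)
        assert a == "p"

    def test_exact_splice_recovered(self, tm):
        rng = np.random.default_rng(34)
        parents = [WeightedSequence(f"p{i}", rand_seq(rng, 60), 20.0) for i in range(4)]
        query = WeightedSequence("q", parents[1].seq[:30] + parents[3].seq[30:], 2.0)
        a, b, bp, dc, dp = find_best_parents(query, parents, tm)
        assert {a, b} == {"p1", "p3"}
        # the reported breakpoint reproduces the query exactly (it may sit a
        # base or two off 30 where the parents agree around the splice)
        assert query.seq in (
            parents[1].seq[:bp] + parents[3].seq[bp:],
            parents[3].seq[:bp] + parents[1].seq[bp:],
        )
        assert dc < 0.01  # identity-column cost only
        assert dc <= dp

    def test_most_abundant_query_has_no_candidates(self, tm):
        rng = np.random.default_rng(35)
        query = WeightedSequence("q", rand_seq(rng, 40), 100.0)
        pool = [WeightedSequence("p", rand_seq(rng, 40), 10.0)]
        assert find_best_parents(query, pool, tm) is None

    def test_matches_exhaustive_pair_breakpoint_scan(self, tm):
        """Per-side minima equal the explicit pair x breakpoint enumeration."""
        rng = np.random.default_rng(36)
        for trial in range(6):
            parents = [
                WeightedSequence(f"p{i}", rand_seq(rng, 30), 50.0)
                for i in range(int(rng.integers(2, 6)))
            ]
            if trial % 2:
                query_seq = parents[0].seq[:15] + parents[-1].seq[15:]
            else:
                query_seq = rand_seq(rng, 30)
            query = WeightedSequence("q", query_seq, 1.0)
            got = find_best_parents(query, parents, tm)
            want_cost, want_bp, want_li, want_ri = oracle_best_splice(
                query_seq, parents, tm
            )
            assert got is not None
            a, b, bp, dc, dp = got
            assert bp == want_bp
            assert dc * len(query_seq) == pytest.approx(want_cost, rel=1e-12)
            assert {a, b} <= {p.id for p in parents}
            assert {a, b} >= {parents[want_li].id, parents[want_ri].id}


class TestLogistic:
    def test_decision_point_is_half_probability(self):
        model = LogisticModel(alpha=-183.25, beta=10.56)
        assert logistic_predict(model.decision_point, model) == pytest.approx(0.5)
        assert model.decision_point == pytest.approx(17.35, abs=5e-3)

    def test_default_model_at_index_20(self):
        p = logistic_predict(20.0, LogisticModel(-7.5, 0.5))
        assert p == pytest.approx(1.0 / (1.0 + math.exp(-2.5)), rel=1e-12)
        assert p == pytest.approx(0.924, abs=1e-3)

    def test_separated_training_flags_nonconvergence(self):
        samples = [(float(i), False) for i in range(8)] + [
            (15.0 + i, True) for i in range(8)
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model, diag = logistic_train(samples)
        assert diag["separated"]
        assert not diag["converged"]
        assert 7.0 < diag["decision_point"] < 15.0

    def test_parameter_recovery_within_two_se(self):
        rng = np.random.default_rng(37)
        alpha, beta = -7.5, 0.5
        idx = rng.uniform(0, 30, size=5000)
        p = 1.0 / (1.0 + np.exp(-(alpha + beta * idx)))
        labels = rng.random(5000) < p
        model, diag = logistic_train(list(zip(idx, labels)))
        se_a, se_b = diag["standard_errors"]
        assert abs(model.alpha - alpha) < 2 * se_a
        assert abs(model.beta - beta) < 2 * se_b
        assert diag["converged"]

    def test_reversed_labels_give_negative_slope(self):
        samples = [(0.0, True), (1.0, True), (10.0, False), (11.0, False)]
        with pytest.warns(UserWarning, match="beta < 0"):
            model, _ = logistic_train(samples)
        assert model.beta < 0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            logistic_train([(1.0, True), (2.0, True)])


class TestRunPerseus:
    def test_most_abundant_sequence_is_good(self, tm):
        rng = np.random.default_rng(38)
        seqs = [
            WeightedSequence("big", rand_seq(rng, 50), 100.0),
            WeightedSequence("small", rand_seq(rng, 50), 1.0),
        ]
        report = {c.query_id: c for c in run_perseus(seqs, tm)}
        assert report["big"].prob == 0.0
        assert report["big"].call == "good"

    def test_exact_bimera_called_chimeric(self, tm):
        rng = np.random.default_rng(39)
        a, b = rand_seq(rng, 120), rand_seq(rng, 120)
        seqs = [
            WeightedSequence("pa", a, 50.0),
            WeightedSequence("pb", b, 50.0),
            WeightedSequence("chim", a[:60] + b[60:], 5.0),
        ]
        report = {c.query_id: c for c in run_perseus(seqs, tm)}
        chim = report["chim"]
        assert chim.dist_chimera < 0.01
        assert chim.index > 20
        assert chim.call == "chimeric"
        assert {chim.parent_a, chim.parent_b} == {"pa", "pb"}
        assert report["pa"].call == "good" and report["pb"].call == "good"

    def test_distant_sequence_good_regardless_of_index(self, tm):
        rng = np.random.default_rng(40)
        seqs = [
            WeightedSequence("p1", rand_seq(rng, 80), 50.0),
            WeightedSequence("p2", rand_seq(rng, 80), 50.0),
            WeightedSequence("far", rand_seq(rng, 80), 1.0),
        ]
        report = {c.query_id: c for c in run_perseus(seqs, tm)}
        assert report["far"].dist_chimera >= 0.15
        assert report["far"].prob == 0.0
        assert report["far"].call == "good"

    def test_reported_parents_never_lighter_than_query(self, tm):
        rng = np.random.default_rng(41)
        seqs = [
            WeightedSequence(f"s{i}", rand_seq(rng, 60), float(rng.integers(1, 100)))
            for i in range(8)
        ]
        weights = {s.id: s.weight for s in seqs}
        for c in run_perseus(seqs, tm):
            if c.parent_a is not None:
                assert weights[c.parent_a] >= weights[c.query_id]
                assert weights[c.parent_b] >= weights[c.query_id]

    def test_synthetic_sensitivity(self, tm):
        """>= 95% of 200 perfect bimeras flagged; no parent false positives."""
        rng = np.random.default_rng(42)
        parents = [WeightedSequence(f"p{i:02d}", rand_seq(rng, 120), 100.0) for i in range(20)]
        bimeras = []
        seen = set()
        while len(bimeras) < 200:
            i, j = rng.choice(20, size=2, replace=False)
            bp = int(rng.integers(30, 90))
            seq = parents[i].seq[:bp] + parents[j].seq[bp:]
            if seq in seen:
                continue
            seen.add(seq)
            bimeras.append(WeightedSequence(f"b{len(bimeras):03d}", seq, 1.0))
        report = {c.query_id: c for c in run_perseus(parents + bimeras, tm)}
        flagged = sum(1 for b in bimeras if report[b.id].call == "chimeric")
        assert flagged >= 190
        assert all(report[p.id].call == "good" for p in parents)
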