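import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from credrank import (
    AnnotationRecord,
    CredibilityLabel,
    SentenceRecord,
    context_stats,
    label_distribution,
    lift_at,
    lift_curve,
    random_baseline_lift,
    recall_at,
)
from credrank.evaluation import EvaluationError

C, N, U = CredibilityLabel.CRED, CredibilityLabel.NONCRED, CredibilityLabel.NEU


def _gold(labels):
    return {f"s{i}": lab for i, lab in enumerate(labels)}


def _order(gold):
    return list(gold)


class TestRecallAndLift:
    # noncredible at ranks 1, 2, 5, 9 of a 10-sentence corpus
    gold = _gold([N, N, C, C, N, C, C, C, N, C])

    def test_recall_counts_noncredible_in_prefix(self):
        assert recall_at(_order(self.gold), self.gold, 5) == pytest.approx(3 / 4)

    def test_recall_at_full_depth_is_one(self):
        assert recall_at(_order(self.gold), self.gold, 10) == 1.0

    def test_recall_zero_when_no_hits_in_prefix(self):
        order = ["s2", "s3", "s5"] + [s for s in self.gold if s not in {"s2", "s3", "s5"}]
        assert recall_at(order, self.gold, 3) == 0.0

    def test_lift_brute_force_value(self):
        assert lift_at(_order(self.gold), self.gold, 5) == pytest.approx(1.5)

    def test_lift_at_full_depth_is_exactly_one(self):
        assert lift_at(_order(self.gold), self.gold, 10) == 1.0

    def test_perfect_ranking_lift(self):
        gold = _gold([N] * 20 + [C] * 80)
        assert lift_at(_order(gold), gold, 20) == pytest.approx(5.0)

    def test_undefined_without_noncredible(self):
        gold = _gold([C, C, U])
        with pytest.raises(EvaluationError):
            recall_at(_order(gold), gold, 2)

    def test_p_out_of_range(self):
        with pytest.raises(EvaluationError):
            recall_at(_order(self.gold), self.gold, 0)
        with pytest.raises(EvaluationError):
            recall_at(_order(self.gold), self.gold, 11)

    @given(
        n=st.integers(2, 50),
        frac=st.floats(0.05, 0.9),
        seed=st.integers(0, 10_000),
    )
    def test_matches_independent_brute_force(self, n, frac, seed):
        """lift agrees with a count-and-divide oracle on random instances."""
        rng = np.random.default_rng(seed)
        labels = [N if rng.random() < frac else C for _ in range(n)]
        if N not in labels:
            labels[rng.integers(0, n)] = N
        gold = _gold(labels)
        order = list(gold)
        rng.shuffle(order)
        p = int(rng.integers(1, n + 1))
        hits = sum(1 for sid in order[:p] if gold[sid] is N)
        nn = sum(1 for lab in labels if lab is N)
        assert lift_at(order, gold, p) == pytest.approx((n / p) * hits / nn)

    def test_perfect_order_maximal_at_every_depth_exhaustively(self):
        """For a tiny corpus, no permutation beats the perfect order at any
        depth (checked over all orders, N <= 8)."""
        gold = _gold([N, N, C, C, U, C])
        ids = list(gold)
        perfect = sorted(ids, key=lambda s: gold[s] is not N)
        for perm in itertools.permutations(ids):
            for p in range(1, len(ids) + 1):
                assert lift_at(perfect, gold, p) >= lift_at(list(perm), gold, p)


class TestRandomBaseline:
    def test_monte_carlo_mean_is_one_within_3_se(self):
        rng = np.random.default_rng(0)
        labels = [N if rng.random() < 0.18 else C for _ in range(500)]
        gold = _gold(labels)
        mean, sd = random_baseline_lift(gold, p=50, n_permutations=400, seed=7)
        assert abs(mean - 1.0) <= 3 * sd / np.sqrt(400) + 1e-9

    def test_single_permutation_reproducible(self):
        gold = _gold([N, C, C, N, C, U])
        a = random_baseline_lift(gold, 3, n_permutations=1, seed=5)
        b = random_baseline_lift(gold, 3, n_permutations=1, seed=5)
        assert a == b

    def test_all_noncredible_gives_lift_exactly_one(self):
        gold = _gold([N] * 40)
        for p in (1, 7, 40):
            mean, sd = random_baseline_lift(gold, p, n_permutations=20, seed=3)
            assert mean == pytest.approx(1.0, abs=1e-12)
            assert sd == pytest.approx(0.0, abs=1e-12)


def test_lift_curve_points_and_invariants():
    gold = _gold([N, N, C, C, N, C, C, C, N, C])
    curve = lift_curve(_order(gold), gold, percentiles=(10, 50, 100))
    df = curve.to_frame()
    assert list(df["p"]) == [1, 5, 10]
    recalls = list(df["recall"])
    assert recalls == sorted(recalls)  # recall non-decreasing in p
    assert df["lift"].iloc[-1] == 1.0
    assert curve.Nn == 4


class TestContextStats:
    def test_bucket_counts_and_percentages(self):
        anns = [AnnotationRecord(f"s{i}", C, context_needed=c) for i, c in enumerate([0, 0, 1, 2])]
        df = context_stats(anns)
        al = df[df["subset"] == "ALL"].set_index("context_needed")
        assert al.loc["0", "count"] == 2 and al.loc["0", "percent"] == 50.0
        assert al.loc["1", "count"] == 1 and al.loc["1", "percent"] == 25.0
        assert al.loc["2", "count"] == 1 and al.loc["2", "percent"] == 25.0

    def test_per_label_subsets_and_overflow_bucket(self):
        anns = [
            AnnotationRecord("a", N, context_needed=0),
            AnnotationRecord("b", N, context_needed=5),
            AnnotationRecord("c", C, context_needed=1),
        ]
        df = context_stats(anns)
        nc = df[df["subset"] == "NONCRED"].set_index("context_needed")
        assert nc.loc["0", "percent"] == 50.0
        assert nc.loc[">3", "count"] == 1
        assert "NEU" not in set(df["subset"])

    def test_empty_input_gives_empty_table(self):
        assert context_stats([]).empty


class TestLabelDistribution:
    def test_toy_topic_proportions(self):
        records = [SentenceRecord(f"s{i}", "x", "statins") for i in range(4)]
        anns = [AnnotationRecord(f"s{i}", lab) for i, lab in enumerate([C, C, N, U])]
        df = label_distribution(anns, records).set_index("topic")
        assert df.loc["statins", "prop_CRED"] == 0.5
        assert df.loc["statins", "prop_NONCRED"] == 0.25
        assert df.loc["statins", "prop_NEU"] == 0.25

    def test_proportions_sum_to_one_per_topic(self):
        rng = np.random.default_rng(8)
        records, anns = [], []
        for i in range(60):
            topic = f"topic_{rng.integers(0, 4)}"
            records.append(SentenceRecord(f"s{i}", "x", topic))
            anns.append(AnnotationRecord(f"s{i}", [C, N, U][rng.integers(0, 3)]))
        df = label_distribution(anns, records)
        sums = df["prop_CRED"] + df["prop_NONCRED"] + df["prop_NEU"]
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)
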