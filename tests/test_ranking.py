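import math

import numpy as np
import pytest

from credrank import (
    CredibilityLabel,
    LabelProbs,
    RankingConfig,
    estimate_probs,
    rank_corpus,
    score_cluster,
)
from credrank.clustering import ClusterModel
from credrank.ranking import UNIFORM_PRIOR, RankingError

C, N, U = CredibilityLabel.CRED, CredibilityLabel.NONCRED, CredibilityLabel.NEU


class TestEstimateProbs:
    def test_empirical_fractions(self):
        p = estimate_probs([N, N, C, U, N])
        assert (p.p_n, p.p_c, p.p_u) == pytest.approx((0.6, 0.2, 0.2), abs=1e-12)
        assert p.n_annotated == 5

    def test_fallback_prior_when_unannotated(self):
        prior = LabelProbs(0.55, 0.18, 0.27)
        p = estimate_probs([], prior)
        assert (p.p_c, p.p_n, p.p_u) == (0.55, 0.18, 0.27)
        assert p.n_annotated == 0

    def test_neutral_share_is_residual(self):
        # 5 noncredible and 4 credible of 10 labels leave p_u = 0.1
        p = estimate_probs([N] * 5 + [C] * 4 + [U])
        assert p.p_n == pytest.approx(0.5)
        assert p.p_c == pytest.approx(0.4)
        assert p.p_u == pytest.approx(0.1)

    def test_probs_sum_to_one(self):
        assert LabelProbs.from_counts(3, 5, 9).p_c + LabelProbs.from_counts(
            3, 5, 9
        ).p_n + LabelProbs.from_counts(3, 5, 9).p_u == pytest.approx(1.0, abs=1e-12)
        with pytest.raises(RankingError):
            LabelProbs(0.6, 0.6, -0.2)


class TestScoreCluster:
    def test_worked_example_ordering(self):
        """With w=1.5 a cluster at (p_n, p_c) = (0.5, 0.4) outranks one at
        (0.4, 0.3): equal sigmoid terms, smaller neutral penalty."""
        hi = score_cluster(LabelProbs(0.4, 0.5, 0.1), w=1.5)
        lo = score_cluster(LabelProbs(0.3, 0.4, 0.3), w=1.5)
        assert hi.value > lo.value

    def test_worked_example_values(self):
        # independently evaluated: logistic(0.1) + 1.5^-1.1 and + 1.5^-1.3
        hi = score_cluster(LabelProbs(0.4, 0.5, 0.1), w=1.5)
        lo = score_cluster(LabelProbs(0.3, 0.4, 0.3), w=1.5)
        logistic01 = 1 / (1 + math.exp(-0.1))
        assert hi.value == pytest.approx(logistic01 + 1.5**-1.1, abs=1e-12)
        assert lo.value == pytest.approx(logistic01 + 1.5**-1.3, abs=1e-12)
        assert hi.value == pytest.approx(1.1651, abs=1e-4)
        assert lo.value == pytest.approx(1.1153, abs=1e-4)

    def test_tie_without_neutral_term(self):
        hi = score_cluster(LabelProbs(0.4, 0.5, 0.1), w=1.5, neutral_term=False)
        lo = score_cluster(LabelProbs(0.3, 0.4, 0.3), w=1.5, neutral_term=False)
        assert hi.value == pytest.approx(lo.value, abs=1e-15)

    def test_balanced_cluster_closed_form(self):
        for w in (1.1, 1.5, 3.0):
            s = score_cluster(LabelProbs(0.5, 0.5, 0.0), w=w)
            assert s.value == pytest.approx(0.5 + 1 / w, abs=1e-12)

    def test_exp_variant_preserves_worked_example(self):
        hi = score_cluster(LabelProbs(0.4, 0.5, 0.1), w=1.5, first_term="exp")
        lo = score_cluster(LabelProbs(0.3, 0.4, 0.3), w=1.5, first_term="exp")
        assert hi.value > lo.value

    def test_w_must_exceed_one(self):
        with pytest.raises(RankingError):
            score_cluster(UNIFORM_PRIOR, w=1.0)
        with pytest.raises(RankingError):
            RankingConfig(w=0.9)

    @pytest.mark.parametrize("w", [1.1, 1.5, 3.0])
    def test_monotone_in_difference_and_neutral_share(self, w):
        """Score strictly increases in p_n - p_c at fixed p_u, and strictly
        decreases in p_u at fixed difference, across a probability grid."""
        for p_u in np.linspace(0.0, 0.6, 4):
            prev = -np.inf
            for diff in np.linspace(-(1 - p_u), 1 - p_u, 9):
                rest = 1 - p_u
                p_n = (rest + diff) / 2
                p_c = rest - p_n
                v = score_cluster(LabelProbs(p_c, p_n, p_u), w=w).value
                assert v > prev
                prev = v
        for diff in (-0.2, 0.0, 0.3):
            prev = np.inf
            for p_u in np.linspace(0.0, 0.6, 7):
                rest = 1 - p_u
                p_n = (rest + diff) / 2
                p_c = rest - p_n
                v = score_cluster(LabelProbs(p_c, p_n, p_u), w=w).value
                assert v < prev
                prev = v

    def test_value_bounds(self):
        # logistic term in (0, 1), neutral term in (0, 1/w): value in (0, 1 + 1/w)
        for w in (1.1, 1.5, 3.0):
            for p_n, p_c, p_u in [(1, 0, 0), (0, 1, 0), (0, 0, 1), (0.2, 0.3, 0.5)]:
                v = score_cluster(LabelProbs(p_c, p_n, p_u), w=w).value
                assert 0.0 < v < 1.0 + 1.0 / w


def _two_cluster_model():
    return ClusterModel(
        k=2,
        centroids=np.zeros((2, 2)),
        assignment={"a": 0, "b": 0, "c": 1},
        distance={"a": 0.2, "b": 0.1, "c": 0.5},
        inertia=0.0,
        seed=0,
    )


class TestRankCorpus:
    cfg = RankingConfig()

    def test_two_level_sort(self):
        # cluster 0 scores higher (all noncredible) -> [b, a] then [c]
        probs = {0: LabelProbs(0.0, 1.0, 0.0), 1: LabelProbs(1.0, 0.0, 0.0)}
        r = rank_corpus(_two_cluster_model(), probs, set(), self.cfg)
        assert r.order == ["b", "a", "c"]
        assert r.cluster_order == [0, 1]

    def test_annotated_sentences_excluded(self):
        probs = {0: LabelProbs(0.0, 1.0, 0.0), 1: LabelProbs(1.0, 0.0, 0.0)}
        r = rank_corpus(_two_cluster_model(), probs, {"b"}, self.cfg)
        assert r.order == ["a", "c"]

    def test_missing_cluster_probs_rejected(self):
        with pytest.raises(RankingError, match=r"\[1\]"):
            rank_corpus(_two_cluster_model(), {0: UNIFORM_PRIOR}, set(), self.cfg)

    def test_matches_brute_force_sort_on_random_instance(self):
        """Ranking equals an independent flat sort by
        (-cluster score, cluster index, distance, sentence id)."""
        rng = np.random.default_rng(17)
        k, n = 5, 30
        assignment = {f"s{i:02d}": int(rng.integers(0, k)) for i in range(n)}
        distance = {sid: float(rng.uniform(0, 1)) for sid in assignment}
        model = ClusterModel(
            k=k, centroids=np.zeros((k, 2)), assignment=assignment,
            distance=distance, inertia=0.0, seed=0,
        )
        probs = {}
        for c in range(k):
            raw = rng.dirichlet([1, 1, 1])
            probs[c] = LabelProbs(raw[0], raw[1], 1.0 - raw[0] - raw[1])
        r = rank_corpus(model, probs, set(), self.cfg)
        scores = {c: score_cluster(probs[c], self.cfg.w).value for c in range(k)}
        expected = sorted(
            assignment,
            key=lambda sid: (
                -scores[assignment[sid]], assignment[sid], distance[sid], sid,
            ),
        )
        assert r.order == expected
        # stability: recomputation yields the identical order
        assert rank_corpus(model, probs, set(), self.cfg).order == r.order
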