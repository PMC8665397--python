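"""Cluster scoring and the two-level sentence ranking.

Each cluster receives a priority score from its estimated label proportions
``(p_c, p_n, p_u)``:

    score = sigmoid(p_n - p_c) + w^-(p_u + 1),        w > 1

The sigmoid term rewards clusters where noncredible sentences outnumber
credible ones; the second term penalizes clusters rich in neutral content
(which wastes expert time without ever being a catch).  The global ranking
orders clusters by descending score, then sentences within each cluster by
ascending cosine distance to the centroid, so that an expert reading from
the top sees the most central sentences of the most suspicious clusters
first.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import pandas as pd

from .clustering import ClusterModel
from .corpus import CredibilityLabel


class RankingError(ValueError):
    pass


@dataclass(frozen=True)
class LabelProbs:
    """Estimated probabilities that a random cluster sentence is credible
    (``p_c``), noncredible (``p_n``), or neutral (``p_u``); ``n_annotated``
    is the number of labels behind the estimate (0 for a prior)."""

    p_c: float
    p_n: float
    p_u: float
    n_annotated: int = 0

    def __post_init__(self) -> None:
        for name, v in (("p_c", self.p_c), ("p_n", self.p_n), ("p_u", self.p_u)):
            if not (0.0 <= v <= 1.0):
                raise RankingError(f"{name} must be in [0, 1], got {v}")
        if abs(self.p_c + self.p_n + self.p_u - 1.0) > 1e-12:
            raise RankingError(
                f"label probabilities must sum to 1, got {self.p_c + self.p_n + self.p_u!r}"
            )
        if self.n_annotated < 0:
            raise RankingError("n_annotated must be >= 0")

    @classmethod
    def from_counts(cls, n_cred: int, n_noncred: int, n_neu: int) -> "LabelProbs":
        total = n_cred + n_noncred + n_neu
        if total == 0:
            raise RankingError("cannot form label probabilities from zero counts")
        # Normalize via the residual so the sum is exactly 1 in floating point.
        p_c = n_cred / total
        p_n = n_noncred / total
        p_u = min(1.0, max(0.0, 1.0 - p_c - p_n))
        return cls(p_c=p_c, p_n=p_n, p_u=p_u, n_annotated=total)


#: Uninformative prior used for clusters with no annotations before any
#: labels exist at all.
UNIFORM_PRIOR = LabelProbs(p_c=1 / 3, p_n=1 / 3, p_u=1 / 3, n_annotated=0)


@dataclass(frozen=True)
class RankingConfig:
    """Knobs of the scoring and annotation loop.

    w: base of the neutral-penalty term; must exceed 1 for the penalty to be
       monotone decreasing in ``p_u``.
    m: pivot sentences annotated per cluster before the first ranking.
    batch_size: sentences annotated between consecutive rerankings.
    use_all_annotations: when True (default), cluster proportions are
       refreshed from every annotation in the cluster rather than the pivots
       only, improving the estimate as the loop progresses.
    first_term: ``"logistic"`` (default) scores with sigmoid(p_n - p_c);
       ``"exp"`` uses the unbounded exp(p_n - p_c) variant for sensitivity
       checks.  Both produce the same cluster order whenever only the
       difference p_n - p_c varies.
    n_clusters: fixed cluster count for the loop; ``None`` selects k by the
       elbow rule over ``k_range``.
    """

    w: float = 1.5
    m: int = 5
    batch_size: int = 50
    use_all_annotations: bool = True
    seed: int = 0
    first_term: str = "logistic"
    fallback_prior: LabelProbs = UNIFORM_PRIOR
    n_clusters: int | None = None
    k_range: tuple[int, int] = (2, 15)

    def __post_init__(self) -> None:
        if self.w <= 1.0:
            raise RankingError(f"w must be > 1, got {self.w}")
        if self.m < 1:
            raise RankingError("m must be >= 1")
        if self.batch_size < 1:
            raise RankingError("batch_size must be >= 1")
        if self.first_term not in ("logistic", "exp"):
            raise RankingError(f"first_term must be 'logistic' or 'exp', got {self.first_term!r}")


@dataclass(frozen=True)
class ClusterScore:
    value: float
    probs: LabelProbs
    w_used: float


@dataclass
class Ranking:
    """Two-level global priority order over not-yet-annotated sentences."""

    order: list[str]
    cluster_order: list[int]
    scores: dict[int, ClusterScore]

    def to_frame(self, model: ClusterModel) -> pd.DataFrame:
        """Export as a table: rank, sentence_id, cluster, distance, score, probs."""
        rows = []
        for rank, sid in enumerate(self.order, start=1):
            c = model.assignment[sid]
            s = self.scores[c]
            rows.append(
                {
                    "rank": rank,
                    "sentence_id": sid,
                    "cluster": c,
                    "distance": model.distance[sid],
                    "cluster_score": s.value,
                    "p_c": s.probs.p_c,
                    "p_n": s.probs.p_n,
                    "p_u": s.probs.p_u,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "rank",
                "sentence_id",
                "cluster",
                "distance",
                "cluster_score",
                "p_c",
                "p_n",
                "p_u",
            ],
        )


def estimate_probs(
    labels: Iterable[CredibilityLabel], fallback_prior: LabelProbs = UNIFORM_PRIOR
) -> LabelProbs:
    """Empirical label fractions over a cluster's annotated sentences.

    With no annotations the ``fallback_prior`` is returned unchanged (with
    ``n_annotated=0``), keeping unannotated clusters mid-ranked rather than
    artificially first or last.
    """
    counts = {CredibilityLabel.CRED: 0, CredibilityLabel.NONCRED: 0, CredibilityLabel.NEU: 0}
    for lab in labels:
        counts[CredibilityLabel(lab)] += 1
    total = sum(counts.values())
    if total == 0:
        return LabelProbs(
            p_c=fallback_prior.p_c,
            p_n=fallback_prior.p_n,
            p_u=fallback_prior.p_u,
            n_annotated=0,
        )
    return LabelProbs.from_counts(
        counts[CredibilityLabel.CRED],
        counts[CredibilityLabel.NONCRED],
        counts[CredibilityLabel.NEU],
    )


def score_cluster(
    probs: LabelProbs, w: float, first_term: str = "logistic", neutral_term: bool = True
) -> ClusterScore:
    """Priority score of one cluster.

    ``sigmoid(p_n - p_c) + w^-(p_u + 1)`` with ``w > 1``.  Setting
    ``neutral_term=False`` drops the second term (used to demonstrate that
    without it, clusters differing only in ``p_u`` tie).  ``first_term="exp"``
    replaces the sigmoid with ``exp(p_n - p_c)``.
    """
    if w <= 1.0:
        raise RankingError(f"w must be > 1, got {w}")
    x = probs.p_n - probs.p_c
    if first_term == "logistic":
        first = 1.0 / (1.0 + math.exp(-x))
    elif first_term == "exp":
        first = math.exp(x)
    else:
        raise RankingError(f"unknown first_term {first_term!r}")
    second = w ** -(probs.p_u + 1.0) if neutral_term else 0.0
    return ClusterScore(value=first + second, probs=probs, w_used=w)


def rank_corpus(
    model: ClusterModel,
    probs_by_cluster: Mapping[int, LabelProbs],
    annotated_ids: Iterable[str],
    config: RankingConfig,
) -> Ranking:
    """Produce the two-level global ranking of not-yet-annotated sentences.

    Clusters are ordered by descending score (ties toward the smaller
    cluster index); within a cluster, sentences by ascending cosine distance
    to the centroid (ties by sentence id).  Output is deterministic given its
    inputs.
    """
    missing = set(range(model.k)) - set(probs_by_cluster)
    if missing:
        raise RankingError(f"no label probabilities for cluster(s) {sorted(missing)}")
    annotated = set(annotated_ids)
    scores = {
        c: score_cluster(probs_by_cluster[c], config.w, first_term=config.first_term)
        for c in range(model.k)
    }
    cluster_order = sorted(range(model.k), key=lambda c: (-scores[c].value, c))
    order: list[str] = []
    for c in cluster_order:
        members = [sid for sid in model.members(c) if sid not in annotated]
        members.sort(key=lambda sid: (model.distance[sid], sid))
        order.extend(members)
    return Ranking(order=order, cluster_order=cluster_order, scores=scores)
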