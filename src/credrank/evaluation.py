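"""Ranking-quality evaluation via recall and lift, plus descriptive tables.

For a review order over a corpus of ``N`` sentences of which ``Nn`` are
gold-noncredible, recall at depth ``p`` is the fraction of all noncredible
sentences found among the first ``p`` reviewed, and

    lift@p = (N / p) * recall@p

i.e. recall divided by the fraction of the corpus reviewed.  A uniformly
random review order has expected lift 1 at every depth; lift above 1 means
an expert reviewing only the top of the order catches proportionally more
noncredible content than chance — direct time savings.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .corpus import AnnotationRecord, CredibilityLabel, SentenceRecord


class EvaluationError(ValueError):
    pass


GoldLabels = Mapping[str, CredibilityLabel]


def gold_labels_from_records(records: Iterable[SentenceRecord]) -> dict[str, CredibilityLabel]:
    """Extract the gold-label mapping of a corpus; records without a gold
    label are skipped."""
    return {r.sentence_id: r.gold_label for r in records if r.gold_label is not None}


def _counts(gold: GoldLabels) -> tuple[int, int]:
    n = len(gold)
    nn = sum(1 for lab in gold.values() if CredibilityLabel(lab) is CredibilityLabel.NONCRED)
    return n, nn


def recall_at(order: Sequence[str], gold: GoldLabels, p: int) -> float:
    """Fraction of all gold-noncredible sentences within the first ``p`` of
    ``order``.  ``N`` is the corpus size (``len(gold)``), not the length of
    the order.  Raises when no noncredible sentences exist (recall
    undefined) or ``p`` is outside ``[1, N]``."""
    n, nn = _counts(gold)
    if nn == 0:
        raise EvaluationError("recall undefined: no gold-noncredible sentences")
    if not (1 <= p <= n):
        raise EvaluationError(f"p must be in [1, {n}], got {p}")
    hits = sum(
        1
        for sid in order[:p]
        if CredibilityLabel(gold[sid]) is CredibilityLabel.NONCRED
    )
    return hits / nn


def lift_at(order: Sequence[str], gold: GoldLabels, p: int) -> float:
    """``(N / p) * recall@p``: how many times more noncredible sentences the
    order surfaces in its top ``p`` than a random review would."""
    n, _ = _counts(gold)
    return (n / p) * recall_at(order, gold, p)


@dataclass
class LiftCurve:
    """Lift/recall at a grid of review depths."""

    N: int
    Nn: int
    points: list[tuple[int, float, float]]  # (p, recall, lift)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.points, columns=["p", "recall", "lift"])
        df.insert(1, "percent_reviewed", 100.0 * df["p"] / self.N)
        return df


#: Review-depth grid (percent of corpus) used by default for lift curves.
DEFAULT_PERCENTILES = (1, 5, 10, 20, 40, 100)


def lift_curve(
    order: Sequence[str],
    gold: GoldLabels,
    percentiles: Sequence[float] = DEFAULT_PERCENTILES,
) -> LiftCurve:
    """Evaluate lift and recall at each percent-of-corpus depth.

    Depths are converted to absolute sentence counts ``p = round(N * pct /
    100)`` (at least 1).  For a full-permutation order the point at 100%
    always has lift exactly 1.
    """
    n, nn = _counts(gold)
    points = []
    for pct in percentiles:
        p = max(1, min(n, int(round(n * pct / 100.0))))
        r = recall_at(order, gold, p)
        points.append((p, r, (n / p) * r))
    return LiftCurve(N=n, Nn=nn, points=points)


def random_baseline_lift(
    gold: GoldLabels, p: int, n_permutations: int, seed: int
) -> tuple[float, float]:
    """Mean and standard deviation of lift@p over seeded uniform random
    review orders.  The expectation is exactly 1 at every depth; this Monte
    Carlo estimate is the empirical baseline against which a method's lift
    is compared."""
    if n_permutations < 1:
        raise EvaluationError("n_permutations must be >= 1")
    n, nn = _counts(gold)
    if nn == 0:
        raise EvaluationError("lift undefined: no gold-noncredible sentences")
    if not (1 <= p <= n):
        raise EvaluationError(f"p must be in [1, {n}], got {p}")
    is_noncred = np.array(
        [CredibilityLabel(lab) is CredibilityLabel.NONCRED for lab in gold.values()],
        dtype=bool,
    )
    rng = np.random.default_rng(seed)
    lifts = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(n)
        hits = int(np.count_nonzero(is_noncred[perm[:p]]))
        lifts[i] = (n / p) * (hits / nn)
    return float(lifts.mean()), float(lifts.std())


_CONTEXT_BUCKETS = ("0", "1", "2", "3", ">3")


def _bucket(context_needed: int) -> str:
    return str(context_needed) if context_needed <= 3 else ">3"


def context_stats(annotations: Iterable[AnnotationRecord]) -> pd.DataFrame:
    """Counts and percentages of the number of surrounding sentences
    annotators needed, overall and per label.

    Returns a tidy table with columns ``subset`` (ALL or a label),
    ``context_needed`` bucket (0, 1, 2, 3, >3), ``count``, ``percent``.
    Empty input yields an empty table.
    """
    rows = []
    anns = list(annotations)
    if not anns:
        return pd.DataFrame(columns=["subset", "context_needed", "count", "percent"])
    subsets: dict[str, list[AnnotationRecord]] = {"ALL": anns}
    for lab in CredibilityLabel:
        subsets[lab.value] = [a for a in anns if CredibilityLabel(a.label) is lab]
    for name, group in subsets.items():
        total = len(group)
        if total == 0:
            continue
        counts: dict[str, int] = {}
        for a in group:
            b = _bucket(a.context_needed)
            counts[b] = counts.get(b, 0) + 1
        for b in _CONTEXT_BUCKETS:
            if b in counts:
                rows.append(
                    {
                        "subset": name,
                        "context_needed": b,
                        "count": counts[b],
                        "percent": 100.0 * counts[b] / total,
                    }
                )
    return pd.DataFrame(rows, columns=["subset", "context_needed", "count", "percent"])


def label_distribution(
    annotations: Iterable[AnnotationRecord],
    records: Iterable[SentenceRecord],
) -> pd.DataFrame:
    """Per-topic label counts and proportions.

    Topics come from the corpus records; labels from the annotations.
    Proportions sum to 1 within each topic.
    """
    topic_of = {r.sentence_id: r.topic for r in records}
    rows = []
    for a in annotations:
        topic = topic_of.get(a.sentence_id)
        if topic is None:
            raise EvaluationError(f"annotation for unknown sentence {a.sentence_id!r}")
        rows.append({"topic": topic, "label": CredibilityLabel(a.label).value})
    if not rows:
        return pd.DataFrame(
            columns=["topic", "CRED", "NONCRED", "NEU", "n",
                     "prop_CRED", "prop_NONCRED", "prop_NEU"]
        )
    df = pd.DataFrame(rows)
    counts = (
        df.groupby(["topic", "label"]).size().unstack(fill_value=0)
        .reindex(columns=[l.value for l in CredibilityLabel], fill_value=0)
    )
    counts["n"] = counts.sum(axis=1)
    for lab in CredibilityLabel:
        counts[f"prop_{lab.value}"] = counts[lab.value] / counts["n"]
    return counts.reset_index()
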