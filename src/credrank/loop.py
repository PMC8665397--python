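"""The active-annotation loop: cluster once, annotate pivots, rerank, repeat.

The loop alternates expert annotation and reranking:

1. encode the corpus (done upstream; the loop takes a post-processed matrix),
2. cluster with k-means and pick the ``m`` most central pivots per cluster,
3. annotate all pivots (iteration 0),
4. estimate per-cluster label proportions, score clusters, and rerank all
   remaining sentences,
5. annotate the top ``batch_size`` of the ranking, then go to 4,

until the annotation budget is exhausted.  Clustering is computed once and
never refit: reranking reorders sentences using the fixed partition plus the
growing label evidence.  The chronological annotation order recorded in the
:class:`AnnotationLog` is itself the ranking that evaluation measures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Protocol, Sequence, Union, runtime_checkable

from .clustering import ClusterModel, fit_kmeans, pivots, select_k_elbow
from .corpus import (
    AnnotationRecord,
    CredibilityLabel,
    SentenceRecord,
    annotation_from_dict,
    annotation_to_dict,
)
from .embeddings import EmbeddingMatrix
from .ranking import LabelProbs, Ranking, RankingConfig, estimate_probs, rank_corpus


class LoopError(ValueError):
    pass


@runtime_checkable
class OracleContract(Protocol):
    """An annotator: maps a sentence id to an annotation, deterministically."""

    def annotate(self, sentence_id: str) -> AnnotationRecord: ...


class GoldLabelOracle:
    """Simulated expert that reads ``gold_label`` off the corpus records.

    Stands in for a human annotator when replaying or simulating the loop on
    a corpus with known ground truth.
    """

    def __init__(self, records: Sequence[SentenceRecord], annotator_id: str = "oracle"):
        self._labels: dict[str, CredibilityLabel] = {}
        self.annotator_id = annotator_id
        for r in records:
            if r.gold_label is not None:
                self._labels[r.sentence_id] = r.gold_label

    def annotate(self, sentence_id: str) -> AnnotationRecord:
        label = self._labels.get(sentence_id)
        if label is None:
            raise LoopError(f"oracle has no gold label for sentence {sentence_id!r}")
        return AnnotationRecord(
            sentence_id=sentence_id, label=label, annotator_id=self.annotator_id
        )


@dataclass
class LogEntry:
    iteration: int
    sentence_id: str
    annotation: AnnotationRecord


@dataclass
class AnnotationLog:
    """Chronological record of the loop's annotations.

    Invariants: no sentence annotated twice; iteration indices non-decreasing.
    """

    entries: list[LogEntry] = field(default_factory=list)
    config: Optional[RankingConfig] = None
    seed: int = 0

    def annotated_ids(self) -> set[str]:
        return {e.sentence_id for e in self.entries}

    def validate(self) -> None:
        seen: set[str] = set()
        last_iter = -1
        for e in self.entries:
            if e.sentence_id in seen:
                raise LoopError(f"sentence {e.sentence_id!r} annotated twice in log")
            seen.add(e.sentence_id)
            if e.iteration < last_iter:
                raise LoopError("iteration indices in log are not non-decreasing")
            last_iter = e.iteration

    def save(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        with path.open("w", encoding="utf-8") as fh:
            for e in self.entries:
                fh.write(
                    json.dumps(
                        {
                            "iteration": e.iteration,
                            "sentence_id": e.sentence_id,
                            "annotation": annotation_to_dict(e.annotation),
                        }
                    )
                    + "\n"
                )
        return path

    @classmethod
    def load(cls, path: Union[str, Path]) -> "AnnotationLog":
        log = cls()
        with Path(path).open("r", encoding="utf-8") as fh:
            for raw in fh:
                if not raw.strip():
                    continue
                d = json.loads(raw)
                log.entries.append(
                    LogEntry(
                        iteration=int(d["iteration"]),
                        sentence_id=d["sentence_id"],
                        annotation=annotation_from_dict(d["annotation"]),
                    )
                )
        log.validate()
        return log


def _cluster_probs(
    model: ClusterModel,
    annotations: dict[str, AnnotationRecord],
    pivot_ids: set[str],
    config: RankingConfig,
) -> dict[int, LabelProbs]:
    """Per-cluster label proportions from the annotations gathered so far."""
    overall = [CredibilityLabel(a.label) for a in annotations.values()]
    fallback = (
        estimate_probs(overall, config.fallback_prior) if overall else config.fallback_prior
    )
    by_cluster: dict[int, list[CredibilityLabel]] = {c: [] for c in range(model.k)}
    for sid, a in annotations.items():
        if not config.use_all_annotations and sid not in pivot_ids:
            continue
        c = model.assignment.get(sid)
        if c is not None:
            by_cluster[c].append(CredibilityLabel(a.label))
    return {c: estimate_probs(labs, fallback) for c, labs in by_cluster.items()}


def _fit_model(X: EmbeddingMatrix, config: RankingConfig) -> ClusterModel:
    if config.n_clusters is not None:
        k = config.n_clusters
    else:
        hi = min(config.k_range[1], X.n)
        k = select_k_elbow(X, (config.k_range[0], hi), config.seed).k
    return fit_kmeans(X, k, config.seed)


def run_loop(
    records: Sequence[SentenceRecord],
    X: EmbeddingMatrix,
    oracle: OracleContract,
    budget: int,
    config: RankingConfig,
) -> AnnotationLog:
    """Simulate the assessment loop under an annotation ``budget``.

    Iteration 0 annotates all pivot sentences (``k * m``, capped by the
    budget); each subsequent iteration reranks the remaining sentences from
    the current label evidence and annotates the top ``batch_size``.  Returns
    the chronological :class:`AnnotationLog`; its length is
    ``min(budget, corpus size)``.
    """
    if budget <= 0:
        raise LoopError(f"budget must be positive, got {budget}")
    if budget > len(records):
        raise LoopError(f"budget {budget} exceeds corpus size {len(records)}")
    if not X.postprocessed:
        raise LoopError("embedding matrix must be post-processed before the loop")
    known_ids = set(X.ids)
    for r in records:
        if r.sentence_id not in known_ids:
            raise LoopError(f"no embedding for sentence {r.sentence_id!r}")

    model = _fit_model(X, config)
    pivot_lists = pivots(model, config.m)
    pivot_ids = {sid for lst in pivot_lists.values() for sid in lst}

    log = AnnotationLog(config=config, seed=config.seed)
    annotations: dict[str, AnnotationRecord] = {}

    def annotate(sid: str, iteration: int) -> None:
        a = oracle.annotate(sid)
        annotations[sid] = a
        log.entries.append(LogEntry(iteration=iteration, sentence_id=sid, annotation=a))

    # Iteration 0: pivots, in cluster order then centrality order.
    remaining = budget
    for c in sorted(pivot_lists):
        for sid in pivot_lists[c]:
            if remaining == 0:
                break
            annotate(sid, 0)
            remaining -= 1

    iteration = 1
    while remaining > 0:
        probs = _cluster_probs(model, annotations, pivot_ids, config)
        ranking = rank_corpus(model, probs, annotations.keys(), config)
        batch = ranking.order[: min(config.batch_size, remaining)]
        if not batch:
            break
        for sid in batch:
            annotate(sid, iteration)
        remaining -= len(batch)
        iteration += 1

    log.validate()
    return log


def replay_annotations(log: AnnotationLog) -> list[str]:
    """Sentence ids in chronological annotation order.

    This order is the de-facto ranking the loop produced, and is what lift
    evaluation consumes.
    """
    log.validate()
    return [e.sentence_id for e in log.entries]


def single_shot_ranking(
    records: Sequence[SentenceRecord],
    X: EmbeddingMatrix,
    oracle: OracleContract,
    config: RankingConfig,
) -> tuple[list[str], AnnotationLog]:
    """Rank the whole corpus once from pivot labels only, with no further loop.

    Annotates the ``m`` most central sentences of each cluster, estimates
    cluster proportions from those labels alone, and returns the pivot order
    followed by the single reranking of everything else — a full permutation
    of the corpus suitable for lift-curve evaluation at any depth.
    """
    if not X.postprocessed:
        raise LoopError("embedding matrix must be post-processed before ranking")
    model = _fit_model(X, config)
    pivot_lists = pivots(model, config.m)
    pivot_ids = {sid for lst in pivot_lists.values() for sid in lst}

    log = AnnotationLog(config=config, seed=config.seed)
    annotations: dict[str, AnnotationRecord] = {}
    for c in sorted(pivot_lists):
        for sid in pivot_lists[c]:
            a = oracle.annotate(sid)
            annotations[sid] = a
            log.entries.append(LogEntry(iteration=0, sentence_id=sid, annotation=a))

    probs = _cluster_probs(model, annotations, pivot_ids, config)
    ranking = rank_corpus(model, probs, annotations.keys(), config)
    order = [e.sentence_id for e in log.entries] + ranking.order
    log.validate()
    return order, log
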