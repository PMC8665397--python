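"""Sentence and annotation records, with JSONL/CSV readers and writers.

The unit of credibility assessment is a single sentence.  A corpus is an
ordered collection of :class:`SentenceRecord`; expert (or simulated) judgments
are :class:`AnnotationRecord` objects kept strictly separate from the
``gold_label`` field, which holds dataset ground truth used only by the
simulated oracle and by evaluation.
"""

from __future__ import annotations

import csv
import json
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Optional, Union


class CredibilityLabel(str, Enum):
    """Three-label credibility schema for medical sentences.

    CRED: reliable, verifiable medical information.
    NONCRED: false, unverifiable, outdated, or persuasion contrary to current
    medical recommendations.
    NEU: no factual medical content (questions, off-topic remarks).
    """

    CRED = "CRED"
    NONCRED = "NONCRED"
    NEU = "NEU"


#: Fixed vocabulary of machine-readable reasons an annotator may attach to a
#: NONCRED judgment.
REASON_TAGS: frozenset[str] = frozenset(
    {
        "weak_or_irrelevant_argument",
        "act_against_medical_knowledge",
        "author_lacks_knowledge_or_objectivity",
        "anecdote_or_rumor",
        "unproven_drug_or_therapy_ad",
        "small_sample_research",
        "invalid_numerical_data",
        "outdated_information",
        "incomprehensible_or_ungrammatical",
    }
)


class CorpusError(ValueError):
    """Base class for corpus/annotation validation failures."""


class CorpusParseError(CorpusError):
    def __init__(self, path: Union[str, Path], line: int, message: str):
        self.path = str(path)
        self.line = line
        super().__init__(f"{path}:{line}: {message}")


class DuplicateIdError(CorpusError):
    def __init__(self, sentence_id: str):
        self.sentence_id = sentence_id
        super().__init__(f"duplicate sentence_id {sentence_id!r}")


class EmptyCorpusError(CorpusError):
    pass


class UnknownSentenceError(CorpusError):
    def __init__(self, sentence_id: str):
        self.sentence_id = sentence_id
        super().__init__(f"annotation references unknown sentence_id {sentence_id!r}")


class UnknownLabelError(CorpusError):
    def __init__(self, label: object):
        self.label = label
        super().__init__(
            f"unknown credibility label {label!r}; expected one of "
            f"{sorted(l.value for l in CredibilityLabel)}"
        )


class UnknownReasonTagError(CorpusError):
    def __init__(self, tags: Iterable[str]):
        self.tags = sorted(tags)
        super().__init__(f"unknown reason tag(s) {self.tags}; allowed: {sorted(REASON_TAGS)}")


@dataclass(frozen=True)
class SentenceRecord:
    """One sentence of the corpus.

    ``gold_label`` is the dataset's ground-truth credibility judgment; it is
    consumed only by the simulated annotation oracle and by evaluation, never
    by the ranking pipeline itself.
    """

    sentence_id: str
    text: str
    topic: str
    source_id: Optional[str] = None
    gold_label: Optional[CredibilityLabel] = None

    def __post_init__(self) -> None:
        if not self.sentence_id:
            raise CorpusError("sentence_id must be non-empty")
        if not self.text.strip():
            raise CorpusError(f"text of {self.sentence_id!r} is empty after stripping")


@dataclass(frozen=True)
class AnnotationRecord:
    """A single credibility judgment of one sentence by one annotator.

    ``context_needed`` counts the surrounding sentences the annotator had to
    consult; ``reason_tags`` is only meaningful for NONCRED labels and must be
    drawn from :data:`REASON_TAGS`.
    """

    sentence_id: str
    label: Union[CredibilityLabel, str]
    reason_tags: frozenset[str] = frozenset()
    free_reason: Optional[str] = None
    context_needed: int = 0
    eval_time_ms: Optional[int] = None
    annotator_id: str = "oracle"


def validate_annotation(
    annotation: AnnotationRecord, corpus_ids: Iterable[str]
) -> AnnotationRecord:
    """Check one annotation against the schema and a corpus id set.

    Returns the record with its label normalized to :class:`CredibilityLabel`
    and its reason tags to a frozenset.  Raises a typed error otherwise:
    :class:`UnknownSentenceError`, :class:`UnknownLabelError`,
    :class:`UnknownReasonTagError`, or :class:`CorpusError` for negative
    counts.  No silent coercion beyond enum/set normalization is performed.
    """
    ids = set(corpus_ids)
    if annotation.sentence_id not in ids:
        raise UnknownSentenceError(annotation.sentence_id)
    try:
        label = CredibilityLabel(annotation.label)
    except ValueError:
        raise UnknownLabelError(annotation.label) from None
    tags = frozenset(annotation.reason_tags)
    bad = tags - REASON_TAGS
    if bad:
        raise UnknownReasonTagError(bad)
    if annotation.context_needed < 0:
        raise CorpusError(f"context_needed must be >= 0, got {annotation.context_needed}")
    if annotation.eval_time_ms is not None and annotation.eval_time_ms < 0:
        raise CorpusError(f"eval_time_ms must be >= 0, got {annotation.eval_time_ms}")
    return replace(annotation, label=label, reason_tags=tags)


_CSV_COLUMNS = ("sentence_id", "text", "topic", "source_id", "gold_label")


def _record_to_dict(r: SentenceRecord) -> dict:
    return {
        "sentence_id": r.sentence_id,
        "text": r.text,
        "topic": r.topic,
        "source_id": r.source_id,
        "gold_label": r.gold_label.value if r.gold_label is not None else None,
    }


def _record_from_mapping(d: Mapping, path: Union[str, Path], line: int) -> SentenceRecord:
    try:
        gold = d.get("gold_label")
        if gold in (None, ""):
            gold_label = None
        else:
            try:
                gold_label = CredibilityLabel(gold)
            except ValueError:
                raise UnknownLabelError(gold) from None
        return SentenceRecord(
            sentence_id=str(d["sentence_id"]),
            text=str(d["text"]),
            topic=str(d.get("topic", "")),
            source_id=(d.get("source_id") or None),
            gold_label=gold_label,
        )
    except KeyError as e:
        raise CorpusParseError(path, line, f"missing field {e.args[0]!r}") from None
    except CorpusError as e:
        raise CorpusParseError(path, line, str(e)) from None


def read_corpus(path: Union[str, Path], format: Optional[str] = None) -> list[SentenceRecord]:
    """Read a sentence corpus from a JSONL or CSV file.

    ``format`` is ``"jsonl"`` or ``"csv"``; if omitted it is inferred from the
    file suffix.  Input order is preserved.  Raises
    :class:`CorpusParseError` (with line number), :class:`DuplicateIdError`,
    or :class:`EmptyCorpusError`.
    """
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "jsonl")
    if fmt not in ("jsonl", "csv"):
        raise ValueError(f"unsupported corpus format {fmt!r}")
    records: list[SentenceRecord] = []
    seen: set[str] = set()
    if fmt == "jsonl":
        with path.open("r", encoding="utf-8") as fh:
            for i, raw in enumerate(fh, start=1):
                if not raw.strip():
                    continue
                try:
                    d = json.loads(raw)
                except json.JSONDecodeError as e:
                    raise CorpusParseError(path, i, f"invalid JSON: {e.msg}") from None
                rec = _record_from_mapping(d, path, i)
                if rec.sentence_id in seen:
                    raise DuplicateIdError(rec.sentence_id)
                seen.add(rec.sentence_id)
                records.append(rec)
    else:
        with path.open("r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise EmptyCorpusError(f"{path}: empty csv file (no header)")
            missing = set(("sentence_id", "text")) - set(reader.fieldnames)
            if missing:
                raise CorpusParseError(path, 1, f"missing column(s) {sorted(missing)}")
            for i, row in enumerate(reader, start=2):
                rec = _record_from_mapping(row, path, i)
                if rec.sentence_id in seen:
                    raise DuplicateIdError(rec.sentence_id)
                seen.add(rec.sentence_id)
                records.append(rec)
    if not records:
        raise EmptyCorpusError(f"{path}: corpus contains no records")
    return records


def write_corpus(
    records: Sequence[SentenceRecord], path: Union[str, Path], format: Optional[str] = None
) -> Path:
    """Write a corpus as UTF-8 JSONL or CSV with a deterministic field order.

    The output round-trips through :func:`read_corpus` record for record.
    An empty collection yields a valid empty-corpus file (header only for
    CSV).
    """
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "jsonl")
    if fmt not in ("jsonl", "csv"):
        raise ValueError(f"unsupported corpus format {fmt!r}")
    if fmt == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for r in records:
                fh.write(json.dumps(_record_to_dict(r), ensure_ascii=False) + "\n")
    else:
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_CSV_COLUMNS, quoting=csv.QUOTE_MINIMAL)
            writer.writeheader()
            for r in records:
                d = _record_to_dict(r)
                d = {k: ("" if d[k] is None else d[k]) for k in _CSV_COLUMNS}
                writer.writerow(d)
    return path


def annotation_to_dict(a: AnnotationRecord) -> dict:
    """Serialize an annotation to a plain JSON-compatible dict."""
    label = a.label.value if isinstance(a.label, CredibilityLabel) else a.label
    return {
        "sentence_id": a.sentence_id,
        "label": label,
        "reason_tags": sorted(a.reason_tags),
        "free_reason": a.free_reason,
        "context_needed": a.context_needed,
        "eval_time_ms": a.eval_time_ms,
        "annotator_id": a.annotator_id,
    }


def annotation_from_dict(d: Mapping) -> AnnotationRecord:
    return AnnotationRecord(
        sentence_id=d["sentence_id"],
        label=d["label"],
        reason_tags=frozenset(d.get("reason_tags") or ()),
        free_reason=d.get("free_reason"),
        context_needed=int(d.get("context_needed", 0)),
        eval_time_ms=d.get("eval_time_ms"),
        annotator_id=d.get("annotator_id", "oracle"),
    )
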