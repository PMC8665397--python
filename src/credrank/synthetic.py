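"""Synthetic labeled corpora with the statistical structure the method assumes.

Real expert-annotated medical corpora of this kind show two regularities the
pipeline exploits: (i) overall label prevalences of roughly 55% credible,
18% noncredible, 27% neutral, and (ii) noncredible sentences concentrated in
a minority of semantic clusters, because misinformation claims recur in a
small number of claim categories.  The vector generator emulates exactly
this: Gaussian blobs in embedding space for semantic clusters, a designated
fraction of "misinformation-enriched" clusters with elevated noncredible
probability, and the residual clusters' noncredible rate solved so the
corpus-wide marginals match the prior.

The text generator produces templated placeholder sentences grouped by
claim-category-style topics, suitable for the hash-projection encoder; it
deliberately does not generate realistic misinformation prose.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .corpus import CredibilityLabel, SentenceRecord
from .embeddings import EmbeddingMatrix
from .ranking import LabelProbs


class GeneratorError(ValueError):
    pass


#: Overall label prevalences emulating a real expert-annotated medical corpus.
DEFAULT_LABEL_PRIOR = LabelProbs(p_c=0.55, p_n=0.18, p_u=0.27)


@dataclass(frozen=True)
class GeneratorParams:
    """Conditions of the synthetic corpus.

    n: corpus size (default 2000, a single-topic-sized batch).
    n_clusters: semantic clusters (default 12, one per broad topic).
    dim: embedding dimensionality of the synthetic vectors.
    label_prior: corpus-wide label prevalences (defaults above).
    enrichment: fraction of clusters designated misinformation-enriched.
    enriched_p_n: noncredible probability inside enriched clusters.
    cluster_spread / separation: within-cluster standard deviation and
        between-centroid scale; defaults give well-separated blobs, the
        regime in which semantic clustering is informative.
    """

    n: int = 2000
    n_clusters: int = 12
    dim: int = 16
    label_prior: LabelProbs = DEFAULT_LABEL_PRIOR
    enrichment: float = 0.2
    enriched_p_n: float = 0.6
    cluster_spread: float = 0.25
    separation: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1 or self.n_clusters < 1 or self.dim < 2:
            raise GeneratorError("n >= 1, n_clusters >= 1, dim >= 2 required")
        if self.n_clusters > self.n:
            raise GeneratorError("n_clusters cannot exceed n")
        if not (0.0 <= self.enrichment <= 1.0):
            raise GeneratorError("enrichment must be in [0, 1]")
        if self.enrichment > 0 and not (
            self.label_prior.p_n < self.enriched_p_n <= 1.0
        ):
            raise GeneratorError(
                f"enriched_p_n must lie in ({self.label_prior.p_n}, 1], "
                f"got {self.enriched_p_n}"
            )
        if self.cluster_spread <= 0 or self.separation <= 0:
            raise GeneratorError("cluster_spread and separation must be positive")

    @property
    def n_enriched(self) -> int:
        if self.enrichment == 0:
            return 0
        return max(1, round(self.enrichment * self.n_clusters))


def cluster_label_distributions(params: GeneratorParams) -> list[LabelProbs]:
    """Per-cluster label distributions whose equal-weight mixture matches the
    corpus prior: enriched clusters get ``enriched_p_n``; the residual
    clusters' noncredible rate is solved to balance the marginal, with the
    remaining mass split between CRED and NEU in the prior's ratio."""
    k, e = params.n_clusters, params.n_enriched
    prior = params.label_prior
    if e == 0:
        return [prior] * k
    resid_p_n = (prior.p_n * k - e * params.enriched_p_n) / (k - e) if k > e else 0.0
    if k > e and resid_p_n < 0:
        raise GeneratorError(
            f"infeasible parameters: residual noncredible rate would be "
            f"{resid_p_n:.4f} < 0 (lower enrichment or enriched_p_n)"
        )
    cu = prior.p_c + prior.p_u  # split non-noncredible mass in prior ratio

    def with_p_n(p_n: float) -> LabelProbs:
        rest = 1.0 - p_n
        p_c = rest * prior.p_c / cu
        return LabelProbs(p_c=p_c, p_n=p_n, p_u=1.0 - p_n - p_c)

    dists = [with_p_n(params.enriched_p_n)] * e
    if k > e:
        dists += [with_p_n(resid_p_n)] * (k - e)
    return dists


_LABEL_VALUES = (CredibilityLabel.CRED, CredibilityLabel.NONCRED, CredibilityLabel.NEU)


def generate_vector_corpus(
    params: GeneratorParams,
) -> tuple[list[SentenceRecord], EmbeddingMatrix, dict[str, int]]:
    """Generate a labeled corpus directly in embedding space.

    Returns the sentence records (placeholder text, gold labels), the raw
    (not post-processed) embedding matrix, and the true cluster assignment.
    Deterministic given ``params.seed``.  Clusters ``0 .. n_enriched-1`` are
    the misinformation-enriched ones.
    """
    rng = np.random.default_rng(params.seed)
    k = params.n_clusters
    dists = cluster_label_distributions(params)
    centroids = rng.normal(0.0, params.separation, size=(k, params.dim))
    assignment = rng.integers(0, k, size=params.n)
    vectors = centroids[assignment] + rng.normal(
        0.0, params.cluster_spread, size=(params.n, params.dim)
    )
    records: list[SentenceRecord] = []
    true_assignment: dict[str, int] = {}
    width = len(str(params.n - 1))
    for i in range(params.n):
        c = int(assignment[i])
        d = dists[c]
        label = _LABEL_VALUES[rng.choice(3, p=[d.p_c, d.p_n, d.p_u])]
        sid = f"s{i:0{width}d}"
        records.append(
            SentenceRecord(
                sentence_id=sid,
                text=f"synthetic sentence {i} of cluster {c}",
                topic=f"topic_{c:02d}",
                gold_label=label,
            )
        )
        true_assignment[sid] = c
    X = EmbeddingMatrix(
        ids=[r.sentence_id for r in records],
        vectors=vectors,
        postprocessed=False,
        backend_name=f"synthetic_gaussian(seed={params.seed})",
    )
    return records, X, true_assignment


@dataclass(frozen=True)
class Template:
    """A sentence template: a topic tag, the label its fillings carry, and a
    format string whose ``{slot}`` placeholders are filled from ``slots``."""

    topic: str
    label: CredibilityLabel
    pattern: str
    slots: dict[str, tuple[str, ...]] = field(default_factory=dict)


#: Placeholder template bank whose topics echo recurring claim categories in
#: medical-misinformation corpora (side effects, diet-vs-drugs, industry
#: distrust, ...).  The wording is deliberately schematic, not realistic
#: misinformation prose.
DEFAULT_TEMPLATE_BANK: tuple[Template, ...] = (
    Template(
        "side_effects",
        CredibilityLabel.NONCRED,
        "claim that the {drug} side effects outweigh the benefits for patients",
        {"drug": ("treatment", "medication", "therapy")},
    ),
    Template(
        "diet_vs_drugs",
        CredibilityLabel.NONCRED,
        "claim that {diet} alone works as well as the prescribed medication",
        {"diet": ("a special diet", "a supplement plan", "lifestyle change")},
    ),
    Template(
        "industry_distrust",
        CredibilityLabel.NONCRED,
        "claim that {actor} profit motives drive the prescription guidelines",
        {"actor": ("industry", "corporate", "commercial")},
    ),
    Template(
        "guideline_summary",
        CredibilityLabel.CRED,
        "statement that current guidelines recommend {action} for this condition",
        {"action": ("regular monitoring", "the standard therapy", "risk assessment")},
    ),
    Template(
        "trial_evidence",
        CredibilityLabel.CRED,
        "statement that randomized trials showed {outcome} with the treatment",
        {"outcome": ("reduced risk", "clear benefit", "improved outcomes")},
    ),
    Template(
        "mechanism",
        CredibilityLabel.CRED,
        "statement that the medication works by {mechanism} in the body",
        {"mechanism": ("blocking an enzyme", "lowering synthesis", "reducing levels")},
    ),
    Template(
        "question",
        CredibilityLabel.NEU,
        "question asking whether {thing} matters for everyday health",
        {"thing": ("this number", "the reading", "the measurement")},
    ),
    Template(
        "narrative",
        CredibilityLabel.NEU,
        "remark about {subject} unrelated to any medical fact",
        {"subject": ("the author's day", "a news headline", "the website layout")},
    ),
)


def generate_text_corpus(
    params: GeneratorParams,
    template_bank: Sequence[Template] = DEFAULT_TEMPLATE_BANK,
) -> list[SentenceRecord]:
    """Generate templated placeholder sentences with labels from their
    templates.  Two sentences from one template share most tokens, so the
    hash-projection encoder places them closer than cross-topic pairs.
    Deterministic given ``params.seed``."""
    if not template_bank:
        raise GeneratorError("template bank must be non-empty")
    rng = np.random.default_rng(params.seed)
    records = []
    width = len(str(params.n - 1))
    for i in range(params.n):
        t = template_bank[int(rng.integers(0, len(template_bank)))]
        fills = {
            slot: choices[int(rng.integers(0, len(choices)))]
            for slot, choices in t.slots.items()
        }
        text = t.pattern.format(**fills) + f" (instance {i})"
        records.append(
            SentenceRecord(
                sentence_id=f"t{i:0{width}d}",
                text=text,
                topic=t.topic,
                gold_label=t.label,
            )
        )
    return records
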