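from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from credrank import (
    CredibilityLabel,
    GeneratorParams,
    GoldLabelOracle,
    RankingConfig,
    SentenceRecord,
    generate_vector_corpus,
    gold_labels_from_records,
    lift_at,
    postprocess_embeddings,
    random_baseline_lift,
    replay_annotations,
    run_loop,
)


@pytest.fixture
def toy_records() -> list[SentenceRecord]:
    return [
        SentenceRecord("s1", "statins lower cholesterol", "cholesterol_statins",
                       source_id="doc1", gold_label=CredibilityLabel.CRED),
        SentenceRecord("s2", "statins are a scam invented for profit",
                       "cholesterol_statins", gold_label=CredibilityLabel.NONCRED),
        SentenceRecord("s3", "this is not why I went to medical school",
                       "cholesterol_statins", gold_label=CredibilityLabel.NEU),
        SentenceRecord("s4", 'text with "quotes", commas\nand a newline',
                       "vaccination", gold_label=CredibilityLabel.CRED),
        SentenceRecord("s5", "unicode: zażółć gęślą jaźń — ≥2×", "vaccination"),
    ]


@pytest.fixture(scope="session")
def default_corpus():
    """Default synthetic corpus: records, post-processed matrix, truth."""
    params = GeneratorParams(seed=3)
    records, X, truth = generate_vector_corpus(params)
    return params, records, postprocess_embeddings(X), truth


@pytest.fixture(scope="session")
def loop_signal_runs():
    """Active loop vs random baseline over 20 generator seeds.

    Each run: default enrichment, n=1000 sentences in 10 clusters, budget of
    10% of the corpus (pivots 5 x 10, then batches of 25), lift measured at
    the 10% review depth against a 50-permutation random baseline.
    """
    results = []
    for i in range(20):
        params = GeneratorParams(n=1000, n_clusters=10, seed=100 + i)
        records, X, _ = generate_vector_corpus(params)
        Xp = postprocess_embeddings(X)
        cfg = RankingConfig(n_clusters=10, m=5, batch_size=25, seed=i)
        log = run_loop(records, Xp, GoldLabelOracle(records), budget=100, config=cfg)
        order = replay_annotations(log)
        gold = gold_labels_from_records(records)
        loop_lift = lift_at(order, gold, 100)
        base_mean, _ = random_baseline_lift(gold, 100, n_permutations=50, seed=1000 + i)
        results.append((loop_lift, base_mean))
    return results
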