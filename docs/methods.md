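# Methods

## Problem setting and model

`credrank` addresses annotation triage: given a corpus of N sentences of
which an unknown minority are noncredible medical statements, order the
corpus so that a budget-limited expert annotator encounters as many
noncredible sentences as possible, as early as possible. The method makes a
single structural assumption: semantically similar sentences have correlated
credibility, because misinformation claims recur in a limited number of
claim families (a "statin side effects" cluster is either mostly suspect or
mostly fine). Under that assumption, partial labels inside a semantic
cluster predict the rest of the cluster, and the corpus can be reordered
after every small batch of annotations.

The pipeline is: encode → post-process → cluster (once) → annotate pivots →
(score clusters → rerank → annotate batch)*, with clustering never refit
during the loop — only the per-cluster label estimates change.

### Cluster score

For a cluster with estimated proportions p(c), p(n), p(u) of credible,
noncredible, and neutral sentences:

```
score = σ(p(n) − p(c)) + w^−(p(u) + 1),    σ(x) = 1 / (1 + e^−x),   w > 1
```

The sigmoid term is monotone in the noncredible-minus-credible margin and
bounded in (0, 1); the second term is a strictly decreasing function of the
neutral share, bounded in (0, 1/w). Neutral sentences never pay off for the
annotator (they are neither catches nor informative confirmations), so among
clusters with equal margin the one with fewer neutrals ranks higher. With
the default w = 1.5, a cluster at (p(n), p(c)) = (0.5, 0.4) outranks one at
(0.4, 0.3) — equal margins, different neutral shares — and the two would tie
exactly if the second term were dropped.

A configuration switch (`first_term="exp"`) replaces the sigmoid with the
unbounded `exp(p(n) − p(c))`. The printed form of this score in the
literature reduces algebraically to the exponential, while its accompanying
prose describes a sigmoid ("close to 1", "tends toward zero"); this package
follows the prose as the default because boundedness is what the
description asserts, and keeps the exponential variant for sensitivity
checks. Both variants are strictly monotone in the margin, so cluster
*order* is identical whenever only the margin varies.

### Ranking

Two-level sort: clusters by descending score, sentences within a cluster by
ascending cosine distance to the centroid (central sentences are the most
representative of whatever the cluster's label profile is). Ties break
deterministically: equal-score clusters by ascending cluster index,
equal-distance sentences by ascending sentence id. Already-annotated
sentences are excluded by construction, so the loop never re-requests a
label.

### Label estimation

Cluster proportions are the empirical label fractions of the cluster's
annotated sentences. By default every annotation in the cluster counts
(`use_all_annotations=True`); setting it to `False` restricts the estimate
to pivot sentences, mirroring a single-pass protocol. A cluster with no
annotations receives a fallback prior: the overall empirical distribution of
all annotations so far, or a uniform (1/3, 1/3, 1/3) prior before any exist.
The fallback keeps unannotated clusters mid-ranked — neither artificially
urgent nor buried.

## Embeddings

Any deterministic encoder with a fixed output dimension plugs in. The
built-in hash-projection encoder maps each token to a fixed pseudo-random
Gaussian direction (keyed blake2b hash of the token, so the mapping is
stable across processes) and represents a sentence as the normalized sum of
its token vectors. It captures exactly one thing — token overlap implies
cosine similarity — which is sufficient for the pipeline's logic and for all
tests, with no model download. A sentence-transformers wrapper is provided
for production use and loaded lazily.

Post-processing subtracts the corpus mean and projects out the first
principal axis of the centered matrix (computed once on the full corpus, via
SVD; sign fixed by making the axis's largest-magnitude entry positive). The
top component of sentence-encoder output is typically dominated by
corpus-wide stylistic variation; removing it sharpens semantic cosine
similarity. The number of removed components is configurable (default 1).
Degenerate input — all rows identical — raises a zero-variance error rather
than guessing an axis; rank-1 input legitimately collapses to the zero
matrix.

## Clustering

k-means runs on L2-normalized vectors so Euclidean proximity tracks cosine
similarity (scikit-learn `KMeans`, `n_init=10`, seeded). Per-sentence
distances are reported as cosine distances to the assigned centroid, the
quantity the intra-cluster ranking uses. Empty clusters cannot occur:
scikit-learn relocates the farthest points into any cluster emptied during
Lloyd iterations.

The cluster count is chosen by the elbow rule, operationalized as the point
of maximum perpendicular distance between the (k, inertia) curve and the
chord joining its endpoints; a flat or linear curve (no elbow) and all other
ties resolve toward the smallest candidate k, the cheaper annotation choice.
A warning fires when the pivot set k·m would exceed 15% of the corpus, the
point at which initial annotation cost begins to defeat prioritization.

## Evaluation

`lift@p = (N/p) · recall@p`, where p is an absolute count of reviewed
sentences, N the corpus size (neutral sentences included — they cost review
time even though they can never be catches), and recall the fraction of all
gold-noncredible sentences among the first p of the order. This is the only
reading under which the measure is dimensionless and random review has
expected lift exactly 1 at every depth, which the test suite verifies by
Monte Carlo and which `scripts/acceptance.py` recomputes from scratch. The
default reporting grid is {1, 5, 10, 20, 40, 100}% of the corpus. Recall is
undefined (and raises) when the corpus has no noncredible sentences.

Descriptive reports: per-topic label distributions, and context-need tables
(how many surrounding sentences the annotator consulted, bucketed 0/1/2/3/>3,
overall and per label).

## Synthetic data

The generator emulates the two regularities of real expert-annotated medical
corpora that the method relies on:

- **Marginals.** Default label prior p(c)=0.55, p(n)=0.18, p(u)=0.27 —
  credible at least twice as frequent as noncredible, neutral under 30%.
- **Concentration.** A fraction (`enrichment`, default 0.2) of clusters is
  misinformation-enriched with p(n)=0.6; the remaining clusters' noncredible
  rate is solved so the corpus-wide marginal still matches the prior (with
  the non-noncredible mass split between CRED and NEU in the prior's ratio).
  Infeasible combinations — a negative residual rate — are rejected at
  parameter validation.

Geometry: cluster centroids drawn i.i.d. Gaussian at scale `separation`
(default 1.0), members isotropic Gaussian at `cluster_spread` (default 0.25),
dimension 16, 12 clusters, 2000 sentences by default. These defaults put the
generator in the well-separated regime where semantic clustering is
informative — the regime the method assumes; they are not a stress test of
clustering itself. Placeholder text only; a template-based text generator
produces token-overlap structure for the hash encoder, with topics echoing
recurring misinformation claim families, and deliberately does not produce
realistic misinformation prose.

What passing tests therefore show: the loop's machinery (estimation,
scoring, reranking, budget accounting) converts cluster-level label
concentration into lift. What they do not show: performance on real
embeddings, where cluster separation is weaker, cluster label purity lower,
and the credibility signal only partially aligned with semantic similarity.

## Numerical and design choices

- Probabilities are validated to sum to 1 within 1e-12; empirical fractions
  are built with the neutral share as the clamped residual.
- Post-processing orthogonality is asserted at 1e-8; the removed axis is
  stored on the matrix for audit.
- The loop reranks after every `batch_size` (default 50) annotations, not
  after each one: reranking granularity is a cost knob, and batching bounds
  it without changing the fixed-point behavior.
- Iteration 0 annotates all pivots in cluster order (capped by budget);
  the chronological annotation log is itself the ranking that evaluation
  scores, so |log| = min(budget, N) exactly.
- A single-shot mode (`single_shot_ranking` / `credrank rank`) annotates
  pivots once and emits one full-corpus ranking, for protocols that rank
  once from m·k pivot labels rather than looping.
- Problem sizes in the test suite (corpora of 120–2000 sentences, 20-seed
  replications at n=1000) are chosen so the full suite runs in well under a
  minute while keeping every statistical check at ≥3-standard-error
  resolution.

## Known limitations

- Clustering is fit once; concept drift within a long annotation campaign
  (new claim families appearing) is not modeled.
- One annotation per sentence; no inter-annotator disagreement handling.
- The simulated oracle reads gold labels deterministically — annotator noise,
  fatigue, and context effects are out of scope.
- The elbow rule inherits the usual caveat that smoothly decaying inertia
  curves have weak elbows; the per-k inertia table is returned so a user can
  override k.
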