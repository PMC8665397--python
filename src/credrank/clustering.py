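"""k-means clustering of sentence vectors, elbow-based model selection, and
pivot-sentence extraction.

Clustering runs in Euclidean space on L2-normalized vectors, so Euclidean
proximity tracks cosine similarity; per-sentence distances to the assigned
centroid are reported as cosine distances, the metric used for intra-cluster
ranking downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .embeddings import EmbeddingMatrix


class ClusteringError(ValueError):
    pass


#: Pivot annotation should stay a small fraction of the corpus for the
#: method to save any expert time; warn above this share.
MAX_PIVOT_FRACTION = 0.15


@dataclass
class ClusterModel:
    """Fitted k-means partition of a corpus.

    ``assignment`` maps each sentence id to its cluster index in ``[0, k)``;
    ``distance`` holds the cosine distance of each sentence to its assigned
    centroid (in ``[0, 2]``).
    """

    k: int
    centroids: np.ndarray  # (k, d), in normalized space
    assignment: dict[str, int]
    distance: dict[str, float]
    inertia: float
    seed: int

    def members(self, cluster: int) -> list[str]:
        return [sid for sid, c in self.assignment.items() if c == cluster]

    @property
    def n(self) -> int:
        return len(self.assignment)


def _normalize_rows(vectors: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(vectors, axis=1, keepdims=True)
    safe = np.where(norms > 0, norms, 1.0)
    return vectors / safe


def fit_kmeans(X: EmbeddingMatrix, k: int, seed: int) -> ClusterModel:
    """Cluster the corpus into ``k`` groups with seeded k-means.

    Deterministic given ``(X, k, seed)``.  Raises :class:`ClusteringError`
    for ``k`` outside ``[1, n]`` or non-finite input.  Empty clusters cannot
    occur: scikit-learn relocates the points farthest from their centroids
    into any cluster left empty during Lloyd iterations.
    """
    if not np.all(np.isfinite(X.vectors)):
        raise ClusteringError("non-finite values in embedding matrix")
    n = X.n
    if k < 1 or k > n:
        raise ClusteringError(f"k must be in [1, {n}], got {k}")
    unit = _normalize_rows(X.vectors)
    km = KMeans(n_clusters=k, random_state=int(seed), n_init=10)
    labels = km.fit_predict(unit)
    centroids = km.cluster_centers_
    centroid_unit = _normalize_rows(centroids)
    cos_dist = 1.0 - unit @ centroid_unit.T  # (n, k)
    assignment = {sid: int(c) for sid, c in zip(X.ids, labels)}
    distance = {
        sid: float(np.clip(cos_dist[i, labels[i]], 0.0, 2.0))
        for i, sid in enumerate(X.ids)
    }
    sizes = np.bincount(labels, minlength=k)
    if np.any(sizes == 0):  # pragma: no cover - guarded by sklearn
        raise ClusteringError("empty cluster after fitting")
    return ClusterModel(
        k=k,
        centroids=centroids,
        assignment=assignment,
        distance=distance,
        inertia=float(km.inertia_),
        seed=int(seed),
    )


@dataclass
class ElbowResult:
    k: int
    table: pd.DataFrame  # columns: k, inertia, chord_distance


def select_k_elbow(
    X: EmbeddingMatrix, k_range: tuple[int, int], seed: int
) -> ElbowResult:
    """Choose the cluster count at the elbow of the inertia curve.

    Fits k-means for every k in the inclusive ``k_range`` and returns the k
    whose ``(k, inertia)`` point lies farthest (perpendicular distance) from
    the chord joining the curve's endpoints — the standard operationalization
    of the elbow heuristic.  Ties, including the fully linear curve where all
    distances are zero, resolve toward the smallest k (cheaper annotation).
    The per-k inertia table is returned for audit.
    """
    lo, hi = int(k_range[0]), int(k_range[1])
    ks = list(range(lo, hi + 1))
    if len(ks) < 3:
        raise ClusteringError(
            f"elbow selection needs at least 3 candidate k values, got {len(ks)}"
        )
    if lo < 1 or hi > X.n:
        raise ClusteringError(f"k_range {k_range} outside [1, {X.n}]")
    inertias = np.array([fit_kmeans(X, k, seed).inertia for k in ks], dtype=float)
    best, dists = elbow_point(ks, inertias)
    table = pd.DataFrame({"k": ks, "inertia": inertias, "chord_distance": dists})
    return ElbowResult(k=ks[best], table=table)


def elbow_point(ks: "list[int]", inertias: np.ndarray) -> tuple[int, np.ndarray]:
    """Index of the elbow of an inertia curve and the per-point chord distances.

    The elbow is the point of maximum perpendicular distance from the chord
    joining the curve's endpoints; a flat or exactly linear curve has all
    distances zero, in which case the first (smallest k) index wins.
    """
    inertias = np.asarray(inertias, dtype=float)
    p0 = np.array([ks[0], inertias[0]])
    p1 = np.array([ks[-1], inertias[-1]])
    chord = p1 - p0
    chord_len = np.linalg.norm(chord)
    pts = np.column_stack([np.asarray(ks, dtype=float), inertias])
    if chord_len == 0:
        dists = np.zeros(len(ks))
    else:
        # 2-D cross product magnitude / chord length = perpendicular distance
        rel = pts - p0
        dists = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0]) / chord_len
    return int(np.argmax(dists)), dists


def pivots(model: ClusterModel, m: int) -> dict[int, list[str]]:
    """Return, per cluster, the up-to-``m`` sentences closest to the centroid.

    These pivot sentences are annotated first to estimate each cluster's
    label distribution.  Lists are sorted by ascending cosine distance
    (ties by sentence id); clusters smaller than ``m`` return all members.
    Warns when the total pivot count exceeds 15% of the corpus.
    """
    if m < 1:
        raise ClusteringError(f"m must be >= 1, got {m}")
    out: dict[int, list[str]] = {}
    for c in range(model.k):
        members = sorted(model.members(c), key=lambda sid: (model.distance[sid], sid))
        out[c] = members[:m]
    total = sum(len(v) for v in out.values())
    if total > MAX_PIVOT_FRACTION * model.n:
        warnings.warn(
            f"pivot set covers {total}/{model.n} sentences "
            f"(> {MAX_PIVOT_FRACTION:.0%} of the corpus); initial annotation cost "
            "may defeat the purpose of prioritization",
            stacklevel=2,
        )
    return out
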