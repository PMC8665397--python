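"""Sentence embeddings: pluggable encoders and principal-component removal.

Any object satisfying :class:`EncoderBackend` (a ``name``, a ``dim``, and a
deterministic ``encode``) can stand behind the pipeline — a transformer
sentence encoder in production, or the dependency-free
:func:`hash_projection_backend` for fully offline runs and tests.

After encoding, the corpus matrix is post-processed by subtracting the
column mean and projecting out the first principal component.  The rationale
is that the dominant direction of variation in sentence-encoder output tends
to carry corpus-wide stylistic/syntactic signal rather than sentence meaning;
removing it sharpens cosine similarity between rows.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Protocol, Sequence, Union, runtime_checkable

import numpy as np

from .corpus import SentenceRecord


class EmbeddingError(ValueError):
    pass


class ZeroVarianceError(EmbeddingError):
    """Raised when post-processing is asked to operate on a zero-variance matrix."""


@runtime_checkable
class EncoderBackend(Protocol):
    """Contract for sentence encoders: deterministic, fixed output dimension."""

    name: str
    dim: int

    def encode(self, texts: Sequence[str]) -> np.ndarray: ...


@dataclass
class EmbeddingMatrix:
    """An n x d matrix of sentence vectors, row i belonging to ``ids[i]``.

    ``postprocessed`` flags whether mean subtraction and component removal
    have been applied; the removed principal axes are retained in
    ``removed_components`` for audit.
    """

    ids: list[str]
    vectors: np.ndarray
    postprocessed: bool = False
    backend_name: str = ""
    removed_components: Optional[np.ndarray] = None  # (r, d) orthonormal rows
    mean: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2:
            raise EmbeddingError("vectors must be a 2-D matrix")
        if len(self.ids) != self.vectors.shape[0]:
            raise EmbeddingError(
                f"{len(self.ids)} ids but {self.vectors.shape[0]} matrix rows"
            )
        if len(set(self.ids)) != len(self.ids):
            raise EmbeddingError("duplicate ids in embedding matrix")
        if not np.all(np.isfinite(self.vectors)):
            raise EmbeddingError("non-finite entries in embedding matrix")

    @property
    def n(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def row(self, sentence_id: str) -> np.ndarray:
        return self.vectors[self.ids.index(sentence_id)]


_TOKEN_RE = re.compile(r"[a-z0-9']+")


def _tokenize(text: str) -> list[str]:
    return _TOKEN_RE.findall(text.lower())


class _HashProjectionBackend:
    """Deterministic, download-free encoder.

    Each token is mapped to a fixed pseudo-random Gaussian direction derived
    from a keyed hash of the token (stable across processes, independent of
    ``PYTHONHASHSEED``); a sentence vector is the L2-normalized sum of its
    token vectors.  Sentences sharing many tokens therefore receive higher
    cosine similarity than token-disjoint ones, which is all the downstream
    pipeline requires of an encoder.
    """

    def __init__(self, dim: int, seed: int):
        if dim < 2:
            raise EmbeddingError(f"hash projection backend needs dim >= 2, got {dim}")
        self.dim = int(dim)
        self.seed = int(seed)
        self.name = f"hash_projection(dim={dim}, seed={seed})"
        self._token_cache: dict[str, np.ndarray] = {}

    def _token_vector(self, token: str) -> np.ndarray:
        vec = self._token_cache.get(token)
        if vec is None:
            digest = hashlib.blake2b(
                token.encode("utf-8"),
                digest_size=8,
                key=str(self.seed).encode("ascii"),
            ).digest()
            rng = np.random.default_rng(int.from_bytes(digest, "big"))
            vec = rng.standard_normal(self.dim)
            self._token_cache[token] = vec
        return vec

    def encode(self, texts: Sequence[str]) -> np.ndarray:
        out = np.zeros((len(texts), self.dim))
        for i, text in enumerate(texts):
            tokens = _tokenize(text)
            if tokens:
                v = np.sum([self._token_vector(t) for t in tokens], axis=0)
                norm = np.linalg.norm(v)
                if norm > 0:
                    v = v / norm
                out[i] = v
        return out


def hash_projection_backend(dim: int, seed: int) -> EncoderBackend:
    """Build the seeded hash-projection encoder (see :class:`_HashProjectionBackend`)."""
    return _HashProjectionBackend(dim, seed)


def sentence_transformer_backend(model_name: str) -> EncoderBackend:
    """Wrap a sentence-transformers checkpoint as an :class:`EncoderBackend`.

    Imported lazily; requires the optional ``sentence-transformers``
    dependency and a locally available checkpoint.
    """
    from sentence_transformers import SentenceTransformer  # pragma: no cover

    class _STBackend:  # pragma: no cover - requires model download
        def __init__(self, model_name: str):
            self._model = SentenceTransformer(model_name)
            self.name = f"sentence_transformer({model_name})"
            self.dim = self._model.get_sentence_embedding_dimension()

        def encode(self, texts: Sequence[str]) -> np.ndarray:
            return np.asarray(self._model.encode(list(texts)), dtype=np.float64)

    return _STBackend(model_name)


def embed_corpus(
    records: Sequence[SentenceRecord],
    backend: EncoderBackend,
    batch_size: int = 256,
) -> EmbeddingMatrix:
    """Encode a corpus, preserving record order; output is not post-processed.

    Encoder failures are re-raised with the offending batch range attached.
    """
    if len(records) == 0:
        raise EmbeddingError("cannot embed an empty corpus")
    ids = [r.sentence_id for r in records]
    texts = [r.text for r in records]
    chunks = []
    for start in range(0, len(texts), batch_size):
        batch = texts[start : start + batch_size]
        try:
            chunk = np.asarray(backend.encode(batch), dtype=np.float64)
        except Exception as e:
            raise EmbeddingError(
                f"encoder {backend.name!r} failed on batch "
                f"[{start}:{start + len(batch)}]: {e}"
            ) from e
        if chunk.shape != (len(batch), backend.dim):
            raise EmbeddingError(
                f"encoder {backend.name!r} returned shape {chunk.shape}, "
                f"expected {(len(batch), backend.dim)}"
            )
        chunks.append(chunk)
    return EmbeddingMatrix(
        ids=ids, vectors=np.vstack(chunks), postprocessed=False, backend_name=backend.name
    )


def postprocess_embeddings(X: EmbeddingMatrix, n_components: int = 1) -> EmbeddingMatrix:
    """Subtract the column mean and remove the top principal component(s).

    Output rows are ``(x - mean) - sum_j ((x - mean) . u_j) u_j`` over the top
    ``n_components`` principal axes ``u_j`` of the mean-centered corpus
    matrix (default 1).  The sign of each axis is fixed by making its
    largest-magnitude entry positive so that results are reproducible across
    linear-algebra backends.  The removed axes and mean are stored on the
    result for audit.

    Raises :class:`ZeroVarianceError` when all rows are identical (no
    principal direction exists) and :class:`EmbeddingError` when the input is
    already post-processed or has fewer than 2 rows.
    """
    if X.postprocessed:
        raise EmbeddingError("embedding matrix is already post-processed")
    if X.n < 2:
        raise EmbeddingError("post-processing requires at least 2 rows")
    if n_components < 1 or n_components >= X.dim:
        raise EmbeddingError(f"n_components must be in [1, dim), got {n_components}")
    mean = X.vectors.mean(axis=0)
    centered = X.vectors - mean
    # SVD of the centered matrix: right singular vectors are principal axes.
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    scale = np.linalg.norm(X.vectors) + 1.0
    if s[0] <= 1e-12 * scale:
        raise ZeroVarianceError(
            "all rows identical: zero variance, no principal component to remove"
        )
    components = vt[:n_components].copy()
    for j in range(components.shape[0]):
        i_max = int(np.argmax(np.abs(components[j])))
        if components[j, i_max] < 0:
            components[j] = -components[j]
    projected = centered - (centered @ components.T) @ components
    return EmbeddingMatrix(
        ids=list(X.ids),
        vectors=projected,
        postprocessed=True,
        backend_name=X.backend_name,
        removed_components=components,
        mean=mean,
    )


def save_embeddings(X: EmbeddingMatrix, matrix_path: Union[str, Path]) -> Path:
    """Persist a matrix as TSV plus a ``.json`` sidecar with ids and metadata."""
    matrix_path = Path(matrix_path)
    np.savetxt(matrix_path, X.vectors, delimiter="\t", fmt="%.17g")
    sidecar = {
        "ids": X.ids,
        "dim": X.dim,
        "backend": X.backend_name,
        "postprocessed": X.postprocessed,
    }
    sidecar_path = matrix_path.with_suffix(matrix_path.suffix + ".json")
    sidecar_path.write_text(json.dumps(sidecar), encoding="utf-8")
    return matrix_path


def load_embeddings(matrix_path: Union[str, Path]) -> EmbeddingMatrix:
    matrix_path = Path(matrix_path)
    sidecar_path = matrix_path.with_suffix(matrix_path.suffix + ".json")
    meta = json.loads(sidecar_path.read_text(encoding="utf-8"))
    vectors = np.loadtxt(matrix_path, delimiter="\t", ndmin=2)
    return EmbeddingMatrix(
        ids=list(meta["ids"]),
        vectors=vectors,
        postprocessed=bool(meta["postprocessed"]),
        backend_name=meta.get("backend", ""),
    )
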