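"""Text-embedding backends and cosine-similarity checks.

Two titles (or abstracts) are compared by embedding each into a fixed-width
vector and taking the cosine. Two backends satisfy the same contract:

* :class:`HashedNgramBackend` — hermetic default: character 3-grams hashed
  into a signed fixed-width vector, L2-normalized. Deterministic, no model
  download, no network; used by the whole test path.
* :class:`SentenceTransformerBackend` — a pretrained biomedical
  sentence-transformer (the model family the published thresholds were tuned
  on). Optional: requires the ``reference`` extra and a model download.

The accept thresholds: titles match at cosine ≥ 0.95, abstracts at cosine
strictly > 0.9 ("exceeds"). Empty text embeds to a zero vector, which can
never pass either check — missing abstracts degrade to a non-match, never a
crash.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from typing import Optional, Protocol, runtime_checkable

import numpy as np

from .errors import UndefinedSimilarityError

__all__ = [
    "EmbeddingBackend",
    "HashedNgramBackend",
    "SentenceTransformerBackend",
    "SimilarityConfig",
    "cosine",
    "titles_similar",
    "abstracts_similar",
]


@runtime_checkable
class EmbeddingBackend(Protocol):
    """Contract: a named backend mapping text to a fixed-width finite vector,
    identical across calls for identical text."""

    name: str
    dim: int

    def embed(self, text: str) -> np.ndarray: ...


_WS = re.compile(r"\s+")


class HashedNgramBackend:
    """Deterministic character 3-gram hashing into a signed, L2-normalized vector.

    Text is lowercased, whitespace-collapsed, and padded with one space on
    each side; each 3-gram is hashed (BLAKE2b, stable across processes) to a
    bucket and a sign, the signed counts are accumulated and the vector is
    L2-normalized. Empty or whitespace-only text yields the zero vector.
    """

    def __init__(self, dim: int = 512, n: int = 3, name: str = "hashed-3gram"):
        if dim < 8:
            raise ValueError("dim must be >= 8")
        self.dim = int(dim)
        self.n = int(n)
        self.name = name
        self._cache: dict[str, np.ndarray] = {}

    def embed(self, text: str) -> np.ndarray:
        cached = self._cache.get(text)
        if cached is not None:
            return cached
        t = _WS.sub(" ", text.lower()).strip()
        vec = np.zeros(self.dim, dtype=np.float64)
        if t:
            padded = f" {t} "
            for i in range(len(padded) - self.n + 1):
                digest = hashlib.blake2b(
                    padded[i : i + self.n].encode("utf-8"), digest_size=8
                ).digest()
                h = int.from_bytes(digest, "little")
                sign = 1.0 if h & 1 else -1.0
                vec[(h >> 1) % self.dim] += sign
            norm = np.linalg.norm(vec)
            if norm > 0:
                vec /= norm
        vec.setflags(write=False)
        if len(self._cache) < 100_000:
            self._cache[text] = vec
        return vec


class SentenceTransformerBackend:
    """Pretrained sentence-embedding backend (optional ``reference`` extra).

    Loads a biomedical sentence-transformer checkpoint by name. Never used in
    the hermetic test path; provided so the tool can run with the embedding
    family its default thresholds were calibrated for.
    """

    def __init__(self, model_name: str, name: str = "sentence-transformer"):
        try:
            from sentence_transformers import SentenceTransformer
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "SentenceTransformerBackend requires the 'reference' extra: "
                "pip install pre2pub[reference]"
            ) from exc
        self._model = SentenceTransformer(model_name)  # pragma: no cover
        self.name = f"{name}:{model_name}"  # pragma: no cover
        self.dim = int(self._model.get_sentence_embedding_dimension())  # pragma: no cover

    def embed(self, text: str) -> np.ndarray:  # pragma: no cover - optional dependency
        if not text.strip():
            return np.zeros(self.dim, dtype=np.float64)
        return np.asarray(self._model.encode([text])[0], dtype=np.float64)


@dataclass(frozen=True)
class SimilarityConfig:
    """Accept thresholds. Title comparison is inclusive (≥), abstract strict (>)."""

    title_threshold: float = 0.95
    abstract_threshold: float = 0.9

    def __post_init__(self) -> None:
        for name in ("title_threshold", "abstract_threshold"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Standard cosine in [-1, 1]. Both vectors zero → undefined (error);
    exactly one zero → 0.0 (guaranteed non-match at any positive threshold)."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"vector length mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 and nv == 0.0:
        raise UndefinedSimilarityError("cosine of two zero vectors is undefined")
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def _score(t1: str, t2: str, backend: EmbeddingBackend) -> Optional[float]:
    if not t1.strip() or not t2.strip():
        return None
    try:
        return cosine(backend.embed(t1), backend.embed(t2))
    except UndefinedSimilarityError:
        return None


def titles_similar(
    t1: str, t2: str, backend: EmbeddingBackend, cfg: SimilarityConfig | None = None
) -> tuple[bool, Optional[float]]:
    """Cosine of the title embeddings against the inclusive title threshold.

    Returns ``(matched, score)``; score is ``None`` when either title is
    empty (the empty-flag path), which never matches.
    """
    cfg = cfg or SimilarityConfig()
    score = _score(t1, t2, backend)
    if score is None:
        return False, None
    return score >= cfg.title_threshold, score


def abstracts_similar(
    a1: str, a2: str, backend: EmbeddingBackend, cfg: SimilarityConfig | None = None
) -> tuple[bool, Optional[float]]:
    """As :func:`titles_similar` but with the *strict* abstract threshold."""
    cfg = cfg or SimilarityConfig()
    score = _score(a1, a2, backend)
    if score is None:
        return False, None
    return score > cfg.abstract_threshold, score
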