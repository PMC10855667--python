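"""Per-token dense vectors from pluggable backends.

Two backends share one contract (``dim``, ``name``, ``embed``): a loader
for pretrained subword embeddings (the 300-dimensional Japanese fastText
model in production) and a seeded hash backend for tests and synthetic
benchmarks.  The hash backend composes seeded pseudo-random unit vectors
keyed by character n-grams, so orthographically related tokens correlate —
the same subword property that lets the pretrained model embed rare
medical terms.  Both backends are deterministic: the same token always
yields a bit-identical vector, across calls and across processes.
"""

from __future__ import annotations

import hashlib
from abc import ABC, abstractmethod

import numpy as np

from .errors import ConfigurationError, InvalidInputError


class EmbeddingBackend(ABC):
    """Deterministic token -> vector map of fixed dimension."""

    dim: int
    name: str

    def embed(self, token: str) -> np.ndarray:
        if not isinstance(token, str) or token == "":
            raise InvalidInputError("cannot embed an empty token")
        vec = np.asarray(self._embed(token), dtype=np.float64)
        if vec.shape != (self.dim,):
            raise ConfigurationError(
                f"backend {self.name!r} returned shape {vec.shape}, expected ({self.dim},)"
            )
        if not np.all(np.isfinite(vec)):
            raise ConfigurationError(f"backend {self.name!r} returned non-finite values")
        return vec

    @abstractmethod
    def _embed(self, token: str) -> np.ndarray: ...


def _char_ngrams(token: str, n_min: int = 2, n_max: int = 4) -> list[str]:
    """Boundary-marked character n-grams plus the whole token.

    The angle-bracket sentinels mirror the usual subword convention so a
    short token is distinguishable from the same string inside a longer one.
    """
    marked = f"<{token}>"
    grams = [token]
    for n in range(n_min, n_max + 1):
        grams.extend(marked[i : i + n] for i in range(len(marked) - n + 1))
    return grams


class HashEmbeddingBackend(EmbeddingBackend):
    """Seeded character-n-gram hash embeddings.

    Each n-gram is mapped to a unit vector drawn from a generator seeded by
    a stable (process-independent) digest of the n-gram and the backend
    seed; the token vector is the L2-normalized mean over its n-grams.
    Tokens sharing n-grams therefore share vector components, giving the
    stub the qualitative geometry of subword embeddings at any dimension.
    """

    def __init__(self, dim: int = 64, seed: int = 0) -> None:
        if dim < 2:
            raise ConfigurationError(f"embedding dim must be >= 2, got {dim}")
        self.dim = int(dim)
        self.seed = int(seed)
        self.name = f"hash(dim={dim},seed={seed})"
        self._cache: dict[str, np.ndarray] = {}

    def _gram_vector(self, gram: str) -> np.ndarray:
        digest = hashlib.blake2b(
            gram.encode("utf-8"), digest_size=8, key=str(self.seed).encode()
        ).digest()
        rng = np.random.Generator(np.random.PCG64(int.from_bytes(digest, "little")))
        v = rng.standard_normal(self.dim)
        return v / np.linalg.norm(v)

    def _embed(self, token: str) -> np.ndarray:
        cached = self._cache.get(token)
        if cached is not None:
            return cached
        grams = _char_ngrams(token)
        v = np.mean([self._gram_vector(g) for g in grams], axis=0)
        norm = np.linalg.norm(v)
        if norm == 0.0:  # astronomically unlikely cancellation; keep contract total
            v = self._gram_vector(token)
            norm = 1.0
        v = v / norm
        v.setflags(write=False)
        self._cache[token] = v
        return v


def make_hash_backend(dim: int = 64, seed: int = 0) -> HashEmbeddingBackend:
    """Construct the seeded hash backend (test/synthetic stand-in)."""
    return HashEmbeddingBackend(dim=dim, seed=seed)


class FastTextBackend(EmbeddingBackend):
    """Lazy loader for a pretrained fastText binary model.

    The production configuration uses the 300-dimensional Japanese model
    (``cc.ja.300.bin``).  Loading requires either the ``fasttext`` package
    or gensim's facebook-format reader; the model file is never bundled.
    """

    def __init__(self, model_path: str) -> None:
        self._model = None
        self._kind = ""
        try:
            import fasttext  # type: ignore

            self._model = fasttext.load_model(model_path)
            self._kind = "fasttext"
            self.dim = int(self._model.get_dimension())
        except ImportError:
            try:
                from gensim.models.fasttext import load_facebook_vectors  # type: ignore

                self._model = load_facebook_vectors(model_path)
                self._kind = "gensim"
                self.dim = int(self._model.vector_size)
            except ImportError as exc:
                raise ConfigurationError(
                    "loading a pretrained subword model requires the 'fasttext' "
                    "or 'gensim' package; install one or use the hash backend"
                ) from exc
        self.name = f"fasttext({model_path})"

    def _embed(self, token: str) -> np.ndarray:
        if self._kind == "fasttext":
            return np.asarray(self._model.get_word_vector(token), dtype=np.float64)
        return np.asarray(self._model[token], dtype=np.float64)


def get_backend(kind: str = "stub", model_path: str | None = None,
                dim: int = 64, seed: int = 0) -> EmbeddingBackend:
    """Backend factory used by the CLI and config loader."""
    if kind == "stub":
        return make_hash_backend(dim=dim, seed=seed)
    if kind == "fasttext":
        if not model_path:
            raise ConfigurationError("fasttext backend requires a model path")
        return FastTextBackend(model_path)
    raise ConfigurationError(f"unknown backend kind: {kind!r}")
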