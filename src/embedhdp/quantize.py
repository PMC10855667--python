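"""Quantization of embeddings into pseudo-Bag-of-Words documents.

A topic model consumes (term id, count) documents, not dense vectors.  The
bridge treats embedding *dimensions* as pseudo-terms: for each token vector
the L largest non-negative components (default L=10) are kept and scaled
(default x100) so they behave like positive term frequencies.  Raw
components are tiny (0.000x) and nearly identical documents would collapse
to indistinguishable topics without the scaling.  Summing the per-token
pseudo-documents gives one pseudo-BoW per sentence, and the suggestion /
ground-truth pair becomes a two-document corpus over a shared dictionary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .embeddings import EmbeddingBackend
from .errors import ConfigurationError, DegenerateDocumentError, InvalidInputError
from .textproc import TokenizedSentence


@dataclass(frozen=True)
class QuantizeConfig:
    """Knobs of the vector -> pseudo-BoW conversion.

    L is the fixed BoW length cap per quantized vector; scale multiplies
    the surviving components; negative components are clipped to zero by
    default (scaling alone cannot make them positive), with an
    absolute-value mode available.
    """

    L: int = 10
    scale: float = 100.0
    negative_handling: str = "clip"

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ConfigurationError(f"L must be >= 1, got {self.L}")
        if not self.scale > 0:
            raise ConfigurationError(f"scale must be > 0, got {self.scale}")
        if self.negative_handling not in ("clip", "absolute"):
            raise ConfigurationError(
                f"negative_handling must be 'clip' or 'absolute', got {self.negative_handling!r}"
            )


@dataclass(frozen=True)
class PseudoBow:
    """Sparse document of (term_id, positive weight) entries.

    Weights are real-valued: rounding the x100-scaled components to
    integers would destroy exactly the small distinctions the scaling
    exists to preserve, and the topic model accepts fractional counts.
    """

    entries: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        ids = [t for t, _ in self.entries]
        if len(ids) != len(set(ids)):
            raise InvalidInputError("duplicate term ids in PseudoBow")
        if any(t < 0 for t in ids):
            raise InvalidInputError("negative term id in PseudoBow")
        if any(not w > 0 for _, w in self.entries):
            raise InvalidInputError("all PseudoBow weights must be strictly positive")

    def __len__(self) -> int:
        return len(self.entries)

    def as_dict(self) -> dict[int, float]:
        return dict(self.entries)

    @property
    def total_weight(self) -> float:
        return float(sum(w for _, w in self.entries))


@dataclass(frozen=True)
class TermDictionary:
    """Bijective pseudo-term <-> contiguous integer id map."""

    id_of: dict[int, int]
    term_of: tuple[int, ...]

    @classmethod
    def from_terms(cls, terms: Iterable[int]) -> "TermDictionary":
        ordered = sorted(set(terms))  # sorted for run-to-run stability
        return cls(id_of={t: i for i, t in enumerate(ordered)}, term_of=tuple(ordered))

    def __len__(self) -> int:
        return len(self.term_of)

    def __contains__(self, term: int) -> bool:
        return term in self.id_of


def quantize_vector(v: np.ndarray, cfg: QuantizeConfig = QuantizeConfig()) -> PseudoBow:
    """Quantize one embedding vector into at most ``cfg.L`` weighted pseudo-terms.

    Pseudo-term ids are the embedding dimension indices of the selected
    components.  Selection keeps the L largest components after negative
    handling; ties break toward the lower dimension index for determinism.
    An all-zero vector yields an empty document — emptiness is policed by
    the callers that assemble sentences, not here.
    """
    v = np.asarray(v, dtype=np.float64)
    if v.ndim != 1:
        raise InvalidInputError(f"expected a 1-d vector, got ndim={v.ndim}")
    if not np.all(np.isfinite(v)):
        raise InvalidInputError("embedding vector contains non-finite values")

    w = np.abs(v) if cfg.negative_handling == "absolute" else np.maximum(v, 0.0)
    # stable sort on the negated values: equal components keep ascending
    # index order, i.e. the lower dimension wins the tie.
    order = np.argsort(-w, kind="stable")[: cfg.L]
    entries = [(int(i), float(cfg.scale * w[i])) for i in order if w[i] > 0.0]
    entries.sort(key=lambda e: e[0])
    return PseudoBow(tuple(entries))


def sentence_bow(
    tokens: TokenizedSentence,
    backend: EmbeddingBackend,
    cfg: QuantizeConfig = QuantizeConfig(),
) -> PseudoBow:
    """Pseudo-BoW of a sentence: element-wise sum of its tokens' quantizations.

    Repeated tokens contribute additively, mirroring term frequency in an
    ordinary bag of words.
    """
    acc: dict[int, float] = {}
    for tok in tokens.tokens:
        for term, weight in quantize_vector(backend.embed(tok), cfg).entries:
            acc[term] = acc.get(term, 0.0) + weight
    if not acc:
        raise DegenerateDocumentError(
            "every token quantized to an empty document; "
            "check the embedding backend and negative_handling"
        )
    return PseudoBow(tuple(sorted(acc.items())))


def load_lexicon(path: str | Path) -> list[str]:
    """Read a domain lexicon: UTF-8, one term per line, '#' comments."""
    terms: list[str] = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        term = line.split("#", 1)[0].strip()
        if term:
            terms.append(term)
    return terms


def build_pair_corpus(
    s1: TokenizedSentence,
    s2: TokenizedSentence,
    backend: EmbeddingBackend,
    cfg: QuantizeConfig = QuantizeConfig(),
    lexicon: Sequence[str] | None = None,
) -> tuple[TermDictionary, list[PseudoBow]]:
    """Assemble the two-document corpus [suggestion, ground truth] and its dictionary.

    The dictionary covers every pseudo-term occurring in either document.
    When a domain lexicon is supplied, the dictionary is additionally
    seeded with the pseudo-terms of each lexicon token, so domain
    vocabulary shapes the term space even when absent from the pair
    (dictionary-augmentation mode).  Document term ids are re-indexed to
    the dictionary's contiguous ids.
    """
    bow1 = sentence_bow(s1, backend, cfg)
    bow2 = sentence_bow(s2, backend, cfg)

    terms: set[int] = {t for t, _ in bow1.entries} | {t for t, _ in bow2.entries}
    if lexicon is not None:
        for term in lexicon:
            terms.update(t for t, _ in quantize_vector(backend.embed(term), cfg).entries)
    dictionary = TermDictionary.from_terms(terms)

    def remap(bow: PseudoBow) -> PseudoBow:
        return PseudoBow(tuple(sorted((dictionary.id_of[t], w) for t, w in bow.entries)))

    return dictionary, [remap(bow1), remap(bow2)]
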