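"""The EmbedHDP similarity score and the sentence-length filter.

One score: tokenize suggestion and ground truth, quantize token embeddings
into a two-document pseudo-BoW corpus, fit the HDP on exactly that corpus,
read off the two topic distributions and return their cosine.  Because the
topic vectors are non-negative the cosine lies in [0, 1].  The companion
length filter drops pairs where either side exceeds ``max_len`` tokens
(default 13): the topic representation degrades on long sentences, so the
benchmark evaluates the metric only in its intended regime.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .embeddings import EmbeddingBackend
from .errors import DegenerateDistributionError, InvalidInputError
from .hdp import HdpParams, TopicDistribution, fit_hdp, topic_distribution
from .quantize import QuantizeConfig, build_pair_corpus, load_lexicon
from .textproc import DEFAULT_PARTICLES, count_words, tokenize


@dataclass(frozen=True)
class PairRecord:
    """One benchmark unit: a generated suggestion, the recorded ground
    truth, and optional per-rater human similarity scores."""

    suggestion: str
    ground_truth: str
    human_scores: tuple[float, ...] | None = None
    id: str = ""

    def __post_init__(self) -> None:
        if self.human_scores is not None:
            scores = tuple(float(s) for s in self.human_scores)
            if not all(np.isfinite(scores)):
                raise InvalidInputError(f"pair {self.id!r}: non-finite human score")
            object.__setattr__(self, "human_scores", scores)


@dataclass(frozen=True)
class MetricConfig:
    """Everything that determines a score, hashable into config_digest."""

    quantize: QuantizeConfig = field(default_factory=QuantizeConfig)
    hdp: HdpParams = field(default_factory=HdpParams)
    tokenizer_mode: str = "whitespace"
    attach_particles: bool = False
    particles: tuple[str, ...] = DEFAULT_PARTICLES
    max_len: int = 13
    lexicon_path: str | None = None

    def __post_init__(self) -> None:
        if self.max_len < 1:
            raise InvalidInputError(f"max_len must be >= 1, got {self.max_len}")

    def digest(self, backend_name: str = "") -> str:
        payload = json.dumps(
            {**asdict(self), "backend": backend_name}, sort_keys=True, ensure_ascii=False
        )
        return hashlib.sha256(payload.encode("utf-8")).hexdigest()[:12]

    def load_lexicon(self) -> list[str] | None:
        if self.lexicon_path is None:
            return None
        return load_lexicon(Path(self.lexicon_path))


@dataclass(frozen=True)
class MetricScore:
    value: float
    metric_name: str
    config_digest: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 1.0):
            raise InvalidInputError(f"metric value {self.value} outside [0, 1]")


def cosine_of_distributions(t1: TopicDistribution, t2: TopicDistribution) -> float:
    """Cosine similarity of two topic distributions; in [0, 1] since both
    are non-negative.  Symmetric; clamped against fp excursions."""
    p1 = np.asarray(t1.proportions, dtype=np.float64)
    p2 = np.asarray(t2.proportions, dtype=np.float64)
    if p1.shape != p2.shape:
        raise InvalidInputError(f"length mismatch: {p1.shape} vs {p2.shape}")
    n1 = np.linalg.norm(p1)
    n2 = np.linalg.norm(p2)
    if n1 == 0.0 or n2 == 0.0:
        raise DegenerateDistributionError("cannot take the cosine of a zero vector")
    return float(np.clip(np.dot(p1, p2) / (n1 * n2), 0.0, 1.0))


def _tokenize_pair(pair: PairRecord, cfg: MetricConfig):
    try:
        s1 = tokenize(pair.suggestion, mode=cfg.tokenizer_mode,
                      attach_particles=cfg.attach_particles, particles=cfg.particles)
        s2 = tokenize(pair.ground_truth, mode=cfg.tokenizer_mode,
                      attach_particles=cfg.attach_particles, particles=cfg.particles)
    except InvalidInputError as exc:
        raise InvalidInputError(f"pair {pair.id!r}: {exc}") from exc
    return s1, s2


def embedhdp_score(
    pair: PairRecord, cfg: MetricConfig, backend: EmbeddingBackend
) -> MetricScore:
    """Score one suggestion / ground-truth pair with EmbedHDP.

    Deterministic given (cfg, backend): the only randomness is the seeded
    HDP initialization fixed in ``cfg.hdp.seed``.  An identical pair yields
    identical documents, hence identical topic distributions and a score
    of 1 up to floating point.
    """
    s1, s2 = _tokenize_pair(pair, cfg)
    dictionary, corpus = build_pair_corpus(
        s1, s2, backend, cfg.quantize, lexicon=cfg.load_lexicon()
    )
    model = fit_hdp(dictionary, corpus, cfg.hdp)
    t1 = topic_distribution(model, corpus[0])
    t2 = topic_distribution(model, corpus[1])
    return MetricScore(
        value=cosine_of_distributions(t1, t2),
        metric_name="embedhdp",
        config_digest=cfg.digest(backend.name),
    )


def length_filter(
    pairs: Sequence[PairRecord], cfg: MetricConfig
) -> tuple[list[PairRecord], list[PairRecord]]:
    """Partition pairs into (kept, removed) by the max_len token rule.

    A pair is removed when either side exceeds ``cfg.max_len`` tokens under
    the active tokenizer configuration; order is preserved within each
    part, and kept + removed is always the whole input.
    """
    kept: list[PairRecord] = []
    removed: list[PairRecord] = []
    for pair in pairs:
        n1 = count_words(pair.suggestion, mode=cfg.tokenizer_mode,
                         attach_particles=cfg.attach_particles, particles=cfg.particles)
        n2 = count_words(pair.ground_truth, mode=cfg.tokenizer_mode,
                         attach_particles=cfg.attach_particles, particles=cfg.particles)
        if n1 > cfg.max_len or n2 > cfg.max_len:
            removed.append(pair)
        else:
            kept.append(pair)
    return kept, removed
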