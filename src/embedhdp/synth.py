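"""Synthetic sentence-pair generator with controllable latent overlap.

Stands in for the caregiver-scored care-record data so every stage of the
pipeline is testable offline.  Each pair has a latent similarity theta in
[0, 1]: the ground truth is drawn from a base vocabulary (occasionally
seeded with a domain-lexicon term), and the suggestion copies a
theta-fraction of its tokens in order, replacing the rest with distractor
tokens from a disjoint vocabulary partition — so theta = 1 reproduces the
ground truth exactly and theta = 0 shares no token with it.  Simulated
raters score theta plus clamped Gaussian noise on [0, 1].  A configurable
share of pairs is built longer than the 13-token filter limit so the
filter path is exercised with known labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from pathlib import Path

import numpy as np
import pandas as pd

from .benchmark import Dataset
from .errors import InvalidInputError
from .metric import PairRecord

#: Pseudo-medical tokens standing in for the curated care-record lexicon.
DEFAULT_LEXICON: tuple[str, ...] = (
    "リハビリテーション", "病院", "感染", "不安", "点眼薬", "発熱", "服薬", "嘔気",
)


@dataclass(frozen=True)
class SynthParams:
    """Generator controls.

    length_range brackets the 13-token filter boundary from below;
    over-limit pairs draw their length from over_length_range instead.
    rater_sd is the per-rater Gaussian noise around theta on the [0, 1]
    human-score scale; three raters mirrors the benchmark's annotation
    setup.
    """

    n_pairs: int = 200
    vocab_size: int = 50
    lexicon_terms: tuple[str, ...] = DEFAULT_LEXICON
    length_range: tuple[int, int] = (3, 13)
    over_length_range: tuple[int, int] = (14, 18)
    frac_over_limit: float = 0.1
    lexicon_prob: float = 0.2
    rater_sd: float = 0.1
    n_raters: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise InvalidInputError("n_pairs must be >= 1")
        if self.vocab_size < 4:
            raise InvalidInputError("vocab_size must be >= 4 to partition pools")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise InvalidInputError(f"bad length_range {self.length_range}")
        if not (0.0 <= self.frac_over_limit <= 1.0):
            raise InvalidInputError("frac_over_limit must be in [0, 1]")
        if self.rater_sd < 0:
            raise InvalidInputError("rater_sd must be >= 0")
        if self.n_raters < 1:
            raise InvalidInputError("n_raters must be >= 1")


def _pools(params: SynthParams) -> tuple[list[str], list[str]]:
    vocab = [f"w{i:03d}" for i in range(params.vocab_size)]
    half = params.vocab_size // 2
    return vocab[:half], vocab[half:]  # (ground pool, distractor pool)


def generate_pair(
    theta: float,
    params: SynthParams,
    rng: np.random.Generator,
    over_limit: bool = False,
    pair_id: str = "",
) -> tuple[PairRecord, float]:
    """Draw one pair at latent overlap ``theta``.

    The suggestion keeps ceil(theta * length) ground-truth tokens in their
    original order — the kept positions are a prefix of one
    theta-independent permutation, so at a fixed generator state a larger
    theta strictly extends the copied set.
    """
    if not (0.0 <= theta <= 1.0):
        raise InvalidInputError(f"theta must be in [0, 1], got {theta}")
    ground_pool, distractor_pool = _pools(params)
    lo, hi = params.over_length_range if over_limit else params.length_range

    length = int(rng.integers(lo, hi + 1))
    ground = [ground_pool[i] for i in rng.integers(0, len(ground_pool), size=length)]
    # Domain-lexicon injection: one medical term per selected sentence.
    if rng.random() < params.lexicon_prob and params.lexicon_terms:
        pos = int(rng.integers(0, length))
        term = params.lexicon_terms[int(rng.integers(0, len(params.lexicon_terms)))]
        ground[pos] = term

    keep = np.zeros(length, dtype=bool)
    perm = rng.permutation(length)
    keep[perm[: ceil(theta * length)]] = True
    distractors = [
        distractor_pool[i] for i in rng.integers(0, len(distractor_pool), size=length)
    ]
    suggestion = [g if k else d for g, d, k in zip(ground, distractors, keep)]

    noise = rng.normal(0.0, params.rater_sd, size=params.n_raters)
    scores = tuple(float(np.clip(theta + e, 0.0, 1.0)) for e in noise)
    record = PairRecord(
        suggestion=" ".join(suggestion),
        ground_truth=" ".join(ground),
        human_scores=scores,
        id=pair_id,
    )
    return record, theta


@dataclass(frozen=True)
class SynthDataset:
    """A generated dataset plus its latent state (theta, over-limit labels)."""

    dataset: Dataset
    latent_theta: tuple[float, ...]
    over_limit: tuple[bool, ...]
    params: SynthParams

    def __post_init__(self) -> None:
        if len(self.latent_theta) != self.dataset.n or len(self.over_limit) != self.dataset.n:
            raise InvalidInputError("latent state length must match dataset size")

    def to_csv(self, path: str | Path) -> None:
        """Write the benchmark CSV schema (round-trips through load_dataset)."""
        rows = []
        for rec in self.dataset.records:
            row = {"id": rec.id, "suggestion": rec.suggestion,
                   "ground_truth": rec.ground_truth}
            for j, s in enumerate(rec.human_scores or (), start=1):
                row[f"human_{j}"] = s
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)


def generate_dataset(params: SynthParams) -> SynthDataset:
    """Generate ``params.n_pairs`` records with uniform latent theta.

    Exactly round(frac_over_limit * n_pairs) pairs are built with both
    sides above the filter limit; which ones is a seeded draw.
    """
    rng = np.random.Generator(np.random.PCG64(params.seed))
    thetas = rng.uniform(0.0, 1.0, size=params.n_pairs)
    n_over = int(round(params.frac_over_limit * params.n_pairs))
    over = np.zeros(params.n_pairs, dtype=bool)
    if n_over:
        over[rng.choice(params.n_pairs, size=n_over, replace=False)] = True

    records = []
    for i in range(params.n_pairs):
        record, _ = generate_pair(
            float(thetas[i]), params, rng,
            over_limit=bool(over[i]), pair_id=f"p{i + 1:04d}",
        )
        records.append(record)
    return SynthDataset(
        dataset=Dataset(tuple(records), source=f"synth(seed={params.seed})"),
        latent_theta=tuple(float(t) for t in thetas),
        over_limit=tuple(bool(o) for o in over),
        params=params,
    )
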