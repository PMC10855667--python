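"""Comparator metrics: sentence-level BLEU, ROUGE-N, ROUGE-L, BoW cosine.

These are the standard surface-overlap scores the topic metric is
benchmarked against, implemented from their definitions.  Care-record
sentences are short, so sentence-level BLEU uses a floor-epsilon smoothing
on zero n-gram precisions (otherwise most scores collapse to 0).  A
BERTScore adapter slot is exposed for callers who have a pretrained
contextual model; no contextual metric is reimplemented here.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from math import exp, fsum, log
from typing import Callable

from .errors import InvalidInputError
from .textproc import TokenizedSentence


@dataclass(frozen=True)
class PrecisionRecallF:
    precision: float
    recall: float
    f: float
    beta: float = 1.0


def _prf(precision: float, recall: float, beta: float = 1.0) -> PrecisionRecallF:
    if precision + recall > 0:
        b2 = beta * beta
        f = (1 + b2) * precision * recall / (b2 * precision + recall)
    else:
        f = 0.0
    return PrecisionRecallF(precision, recall, f, beta)


def _ngrams(tokens: tuple[str, ...], n: int) -> Counter:
    return Counter(tokens[i : i + n] for i in range(len(tokens) - n + 1))


def modified_precision(
    cand: TokenizedSentence, ref: TokenizedSentence, n: int
) -> Fraction:
    """Clipped n-gram precision: each candidate n-gram counts at most as
    often as it appears in the reference."""
    if n < 1:
        raise InvalidInputError(f"n-gram order must be >= 1, got {n}")
    cand_counts = _ngrams(cand.tokens, n)
    total = sum(cand_counts.values())
    if total == 0:
        return Fraction(0)
    ref_counts = _ngrams(ref.tokens, n)
    clipped = sum(min(c, ref_counts[g]) for g, c in cand_counts.items())
    return Fraction(clipped, total)


def bleu(
    cand: TokenizedSentence,
    ref: TokenizedSentence,
    max_n: int = 4,
    smoothing_epsilon: float = 1e-9,
) -> float:
    """Sentence-level BLEU: geometric mean of modified precisions for
    n = 1..max_n times the brevity penalty.

    Zero precisions are floored at ``smoothing_epsilon`` before the log —
    without smoothing, any sentence pair lacking a 4-gram match scores 0.
    The order is additionally capped at the shorter sentence length
    (effective order), so a two-token sentence is scored on unigrams and
    bigrams only; without the cap no short sentence could reach 1, not
    even against itself.  The brevity penalty is 1 for candidates at
    least as long as the reference and exp(1 - r/c) otherwise.
    """
    if max_n < 1:
        raise InvalidInputError(f"max_n must be >= 1, got {max_n}")
    max_n = max(1, min(max_n, cand.n_tokens, ref.n_tokens))
    precisions = [float(modified_precision(cand, ref, n)) for n in range(1, max_n + 1)]
    smoothed = [max(p, smoothing_epsilon) for p in precisions]
    geo_mean = exp(fsum(log(p) for p in smoothed) / max_n)
    c, r = cand.n_tokens, ref.n_tokens
    bp = 1.0 if c > r else exp(1.0 - r / c) if c < r else 1.0
    return min(bp * geo_mean, 1.0)


def rouge_n(
    cand: TokenizedSentence, ref: TokenizedSentence, n: int, beta: float = 1.0
) -> PrecisionRecallF:
    """n-gram overlap recall/precision against the reference."""
    if n < 1:
        raise InvalidInputError(f"n-gram order must be >= 1, got {n}")
    cand_counts = _ngrams(cand.tokens, n)
    ref_counts = _ngrams(ref.tokens, n)
    overlap = sum(min(c, cand_counts[g]) for g, c in ref_counts.items())
    n_cand = sum(cand_counts.values())
    n_ref = sum(ref_counts.values())
    precision = overlap / n_cand if n_cand else 0.0
    recall = overlap / n_ref if n_ref else 0.0
    return _prf(precision, recall, beta)


def lcs_length(a: tuple[str, ...], b: tuple[str, ...]) -> int:
    """Longest common subsequence length by the standard O(|a||b|) DP."""
    prev = [0] * (len(b) + 1)
    for x in a:
        curr = [0]
        for j, y in enumerate(b, 1):
            curr.append(prev[j - 1] + 1 if x == y else max(prev[j], curr[j - 1]))
        prev = curr
    return prev[-1]


def rouge_l(
    cand: TokenizedSentence, ref: TokenizedSentence, beta: float = 1.0
) -> PrecisionRecallF:
    """LCS-based overlap: P = lcs/|cand|, R = lcs/|ref|."""
    ell = lcs_length(cand.tokens, ref.tokens)
    return _prf(ell / cand.n_tokens, ell / ref.n_tokens, beta)


def bow_cosine(s1: TokenizedSentence, s2: TokenizedSentence) -> float:
    """Cosine of term-frequency vectors over the union vocabulary.

    Order-insensitive by construction: permuting a sentence leaves its
    term-frequency vector unchanged.
    """
    c1 = Counter(s1.tokens)
    c2 = Counter(s2.tokens)
    dot = sum(c1[t] * c2[t] for t in c1.keys() & c2.keys())
    n1 = sum(v * v for v in c1.values()) ** 0.5
    n2 = sum(v * v for v in c2.values()) ** 0.5
    return min(dot / (n1 * n2), 1.0)


#: A BERTScore-style adapter is any callable scoring a (candidate,
#: reference) raw-text pair into [0, 1].  Supplying one plugs a pretrained
#: contextual metric into the benchmark panel without this package
#: depending on any deep-learning stack.
SentenceScorer = Callable[[str, str], float]
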