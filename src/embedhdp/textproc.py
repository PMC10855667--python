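"""Tokenization of care-record sentences.

Japanese care-record text is segmented either by a morphological analyzer
(wakati-style surface tokens) or, for pre-segmented / test input, by
whitespace.  Grammatical particles (は, を, の, ...) carry role information
that is lost if they float as standalone tokens, so an explicit post-pass
re-attaches each particle token to its host word.  Lemmatization and
stemming are deliberately not performed.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .errors import InvalidInputError, MissingAnalyzerError

#: Particles and light verbs that are merged into their host word when
#: ``attach_particles`` is on.  User-extensible via the ``particles``
#: argument of :func:`tokenize`.
DEFAULT_PARTICLES: tuple[str, ...] = (
    "は", "へ", "で", "を", "の", "て", "ます", "し", "あり", "ある", "する", "なる",
)


@dataclass(frozen=True)
class TokenizedSentence:
    """An ordered sequence of surface tokens.

    The unique-token *set* views used to build the pair dictionary are
    derived from ``tokens``; order is preserved here because the n-gram
    baselines need it.
    """

    tokens: tuple[str, ...]
    n_tokens: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.tokens:
            raise InvalidInputError("a TokenizedSentence must contain at least one token")
        if any(t == "" for t in self.tokens):
            raise InvalidInputError("empty token in TokenizedSentence")
        object.__setattr__(self, "n_tokens", len(self.tokens))

    def unique(self) -> frozenset[str]:
        return frozenset(self.tokens)


Analyzer = Callable[[str], Sequence[str]]


def _default_morphological_analyzer() -> Analyzer:
    """Locate a MeCab binding at runtime.

    fugashi and mecab-python3 both expose wakati-style surface segmentation;
    whichever imports first wins.  Tests and analyzer-free installs use
    whitespace mode or pass an ``analyzer`` callable instead.
    """
    try:  # pragma: no cover - depends on optional install
        import fugashi  # type: ignore

        tagger = fugashi.Tagger("-Owakati")
        return lambda text: [w.surface for w in tagger(text)]
    except ImportError:
        pass
    try:  # pragma: no cover - depends on optional install
        import MeCab  # type: ignore

        tagger = MeCab.Tagger("-Owakati")
        return lambda text: tagger.parse(text).split()
    except ImportError:
        pass
    raise MissingAnalyzerError(
        "morphological mode needs a MeCab binding (fugashi or mecab-python3) "
        "or an explicit analyzer callable"
    )


def attach_particle_tokens(
    tokens: Sequence[str], particles: Iterable[str] = DEFAULT_PARTICLES
) -> list[str]:
    """Merge each particle token into the preceding token.

    A particle with no predecessor (sentence-initial) is held and merged
    into the following token so that no bare particle survives where a
    host word exists.  Character content is conserved exactly.
    """
    pset = frozenset(particles)
    merged: list[str] = []
    pending = ""  # leading particles waiting for a host
    for tok in tokens:
        if tok in pset:
            if merged:
                merged[-1] += tok
            else:
                pending += tok
        else:
            merged.append(pending + tok)
            pending = ""
    if pending:
        # Sentence consisted entirely of particles; emit them as one token.
        merged.append(pending)
    return merged


def tokenize(
    text: str,
    mode: str = "whitespace",
    attach_particles: bool = False,
    particles: Iterable[str] = DEFAULT_PARTICLES,
    analyzer: Analyzer | None = None,
) -> TokenizedSentence:
    """Segment ``text`` into surface tokens.

    Parameters
    ----------
    text:
        Raw UTF-8 sentence; NFKC-normalized before segmentation so
        full-width and half-width variants coincide.
    mode:
        ``"whitespace"`` splits on runs of whitespace (pre-segmented or
        test input); ``"morphological"`` uses ``analyzer`` or an
        auto-detected MeCab binding.
    attach_particles:
        Apply :func:`attach_particle_tokens` as a post-pass.
    analyzer:
        Override the morphological backend with any callable mapping a
        sentence to a sequence of surface tokens.
    """
    if not isinstance(text, str):
        raise InvalidInputError(f"expected str, got {type(text).__name__}")
    normalized = unicodedata.normalize("NFKC", text).strip()
    if not normalized:
        raise InvalidInputError("cannot tokenize an empty or whitespace-only sentence")

    if mode == "whitespace":
        tokens: Sequence[str] = normalized.split()
    elif mode == "morphological":
        run = analyzer if analyzer is not None else _default_morphological_analyzer()
        tokens = [t for t in run(normalized) if t.strip()]
        if not tokens:
            raise InvalidInputError("analyzer returned no tokens")
    else:
        raise InvalidInputError(f"unknown tokenizer mode: {mode!r}")

    if attach_particles:
        tokens = attach_particle_tokens(tokens, particles)
    return TokenizedSentence(tuple(tokens))


def count_words(
    text: str,
    mode: str = "whitespace",
    attach_particles: bool = False,
    particles: Iterable[str] = DEFAULT_PARTICLES,
    analyzer: Analyzer | None = None,
) -> int:
    """Token count of ``text`` under the given tokenizer configuration.

    This is the quantity the 13-word evaluation filter compares against.
    """
    return tokenize(
        text, mode=mode, attach_particles=attach_particles,
        particles=particles, analyzer=analyzer,
    ).n_tokens
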