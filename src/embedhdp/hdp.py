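"""Hierarchical Dirichlet process topic model over a pair corpus.

The model is the two-level stick-breaking HDP: a corpus-level stick-breaking
draw (concentration ``gamma``) defines global topic weights, each document
draws its own sticks (concentration ``alpha``) over "tables" that point at
global topics, and topics are Dirichlet(``eta``) distributions over the
pseudo-term vocabulary.  The number of topics is not fixed in the model;
``T`` (global) and ``K`` (per-document) are inference-side truncations of
the variational posterior, not model assumptions.

Inference is batch coordinate-ascent variational Bayes with the standard
factorized posterior: Dirichlet topic factors, Beta stick factors at both
levels, multinomial table-to-topic (zeta) and term-to-table (r)
responsibilities.  Fractional term weights (the x100-scaled pseudo-counts)
enter the updates exactly as integer counts would.  All stochasticity is a
single seeded initialization of the topic matrix, so a (corpus, params,
seed) triple reproduces the fitted state bit-for-bit; document-side
factors are initialized deterministically, which makes identical documents
receive identical topic distributions exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, logsumexp

from .errors import (
    ConfigurationError,
    DegenerateDocumentError,
    DictionaryMismatchError,
    InvalidInputError,
)
from .quantize import PseudoBow, TermDictionary


@dataclass(frozen=True)
class HdpParams:
    """Hyperparameters and truncations of the variational HDP.

    gamma and alpha are the corpus- and document-level stick-breaking
    concentrations; eta smooths topic-term Dirichlets (small eta -> sparse,
    well-separated topics); T and K truncate the global and per-document
    posteriors.  K defaults to T so each distinct pseudo-term of a
    document can occupy its own table — a K far below the per-document
    term count forces unrelated terms to share a table and collapses the
    pair score to a same/different indicator.  iterations caps the
    coordinate-ascent sweeps; the fit stops early once the topic matrix
    changes by less than tol between sweeps (still deterministic).
    """

    gamma: float = 1.0
    alpha: float = 1.0
    eta: float = 0.01
    T: int = 150
    K: int = 150
    iterations: int = 100
    seed: int = 0
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if not (self.gamma > 0 and self.alpha > 0 and self.eta > 0):
            raise ConfigurationError("gamma, alpha and eta must all be > 0")
        if self.T < 1 or self.K < 1:
            raise ConfigurationError("truncations T and K must be >= 1")
        if self.K > self.T:
            raise ConfigurationError(f"K ({self.K}) must not exceed T ({self.T})")
        if self.iterations < 1:
            raise ConfigurationError("iterations must be >= 1")
        if self.tol < 0:
            raise ConfigurationError("tol must be >= 0")


@dataclass(frozen=True)
class TopicDistribution:
    """Non-negative topic-proportion vector summing to one."""

    proportions: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=np.float64)
        if p.ndim != 1:
            raise InvalidInputError("topic proportions must be a 1-d vector")
        if np.any(p < 0):
            raise InvalidInputError("topic proportions must be non-negative")
        if abs(p.sum() - 1.0) > 1e-8:
            raise InvalidInputError(f"topic proportions sum to {p.sum()}, not 1")
        p.setflags(write=False)
        object.__setattr__(self, "proportions", p)

    def __len__(self) -> int:
        return len(self.proportions)


# --- stick-breaking helpers -------------------------------------------------
# A truncated stick of `total` segments has `total - 1` Beta factors; the
# last segment takes the remaining mass.  With total == 1 the stick is
# degenerate and all helpers return the obvious constants.


def _elog_sticks(a: np.ndarray, b: np.ndarray, total: int) -> np.ndarray:
    """E[log weight] of each stick segment under Beta(a, b) factors."""
    out = np.zeros(total)
    if total == 1:
        return out
    psi_ab = digamma(a + b)
    elog_w = digamma(a) - psi_ab
    elog_1mw = digamma(b) - psi_ab
    out[: total - 1] = elog_w
    out[1:] += np.cumsum(elog_1mw)
    return out


def _expected_sticks(a: np.ndarray, b: np.ndarray, total: int) -> np.ndarray:
    """E[weight] of each stick segment (exact under the Beta factors)."""
    if total == 1:
        return np.ones(1)
    frac = a / (a + b)
    remaining = np.concatenate([[1.0], np.cumprod(1.0 - frac)])
    out = np.empty(total)
    out[: total - 1] = frac * remaining[: total - 1]
    out[total - 1] = remaining[total - 1]
    return out


def _stick_posteriors(mass: np.ndarray, conc: float) -> tuple[np.ndarray, np.ndarray]:
    """Beta posterior parameters given expected segment usage ``mass``."""
    total = len(mass)
    if total == 1:
        return np.empty(0), np.empty(0)
    suffix = np.cumsum(mass[::-1])[::-1]  # suffix[t] = sum_{s >= t} mass_s
    a = 1.0 + mass[: total - 1]
    b = conc + suffix[1:]
    return a, b


class _DocState:
    """Variational factors of one document during fitting.

    Term-to-table responsibilities are initialized by spreading the
    document's terms round-robin over the K tables (in term-id order).
    A symmetric initialization would leave every table identical, the
    document would collapse onto a single document-specific topic, and
    the pair score would degenerate to a same/different indicator; the
    round-robin seeding differentiates tables by term content so topics
    anchor to terms that both documents can share.  It is a deterministic
    function of the document, so identical documents still receive
    identical factors.
    """

    __slots__ = ("idx", "counts", "weighted", "zeta", "elog_pi", "a", "b")

    def __init__(self, idx: np.ndarray, counts: np.ndarray, params: HdpParams) -> None:
        self.idx = idx
        self.counts = counts
        m = len(idx)
        r0 = np.zeros((m, params.K))
        r0[np.arange(m), np.arange(m) % params.K] = 1.0
        self.weighted = r0 * counts[:, None]  # (m, K) count-weighted resp.
        self.zeta = np.full((params.K, params.T), 1.0 / params.T)
        a0 = np.ones(params.K - 1)
        b0 = np.full(params.K - 1, params.alpha)
        self.a, self.b = a0, b0
        self.elog_pi = _elog_sticks(a0, b0, params.K)


def _doc_sweep(
    doc: _DocState,
    elog_phi: np.ndarray,
    elog_sigma: np.ndarray,
    params: HdpParams,
) -> np.ndarray:
    """One coordinate-ascent sweep over a document's factors.

    Updates tables from the current term responsibilities, then the
    responsibilities from the new tables.  Returns the (m, K)
    count-weighted responsibilities used for the global statistics.
    """
    elog_phi_doc = elog_phi[:, doc.idx]  # (T, m)

    log_zeta = elog_sigma[None, :] + doc.weighted.T @ elog_phi_doc.T  # (K, T)
    log_zeta -= logsumexp(log_zeta, axis=1, keepdims=True)
    doc.zeta = np.exp(log_zeta)

    table_mass = doc.weighted.sum(axis=0)  # (K,)
    doc.a, doc.b = _stick_posteriors(table_mass, params.alpha)
    doc.elog_pi = _elog_sticks(doc.a, doc.b, params.K)

    log_r = doc.elog_pi[None, :] + (doc.zeta @ elog_phi_doc).T  # (m, K)
    log_r -= logsumexp(log_r, axis=1, keepdims=True)
    used = doc.weighted
    doc.weighted = np.exp(log_r) * doc.counts[:, None]
    return used


@dataclass(frozen=True)
class HdpModelState:
    """A fitted HDP: topic-term variational Dirichlet parameters plus sticks."""

    topic_term_weights: np.ndarray  # (T, V) Dirichlet parameters lambda
    elog_phi: np.ndarray            # cached E[log phi], (T, V)
    elog_sigma: np.ndarray          # cached E[log sigma], (T,)
    n_terms: int
    params: HdpParams

    def __post_init__(self) -> None:
        for arr in (self.topic_term_weights, self.elog_phi, self.elog_sigma):
            arr.setflags(write=False)


def _validate_doc(doc: PseudoBow, n_terms: int) -> tuple[np.ndarray, np.ndarray]:
    if len(doc) == 0:
        raise DegenerateDocumentError("cannot fit or query an empty pseudo-BoW document")
    idx = np.array([t for t, _ in doc.entries], dtype=np.intp)
    counts = np.array([w for _, w in doc.entries], dtype=np.float64)
    if idx.min() < 0 or idx.max() >= n_terms:
        raise DictionaryMismatchError(
            f"document references term id {int(idx.max())} outside dictionary of size {n_terms}"
        )
    return idx, counts


def fit_hdp(
    dictionary: TermDictionary,
    corpus: list[PseudoBow],
    params: HdpParams = HdpParams(),
) -> HdpModelState:
    """Fit the variational HDP on ``corpus`` over ``dictionary``.

    The pair metric always fits fresh on exactly the two documents of one
    sentence pair; nothing is shared across pairs.
    """
    if not corpus:
        raise InvalidInputError("corpus must contain at least one document")
    n_terms = len(dictionary)
    if n_terms == 0:
        raise DictionaryMismatchError("empty dictionary")
    docs = [_DocState(*_validate_doc(d, n_terms), params) for d in corpus]

    # Term-anchored initialization: topic k starts with unit mass on
    # vocabulary terms {v : v mod T == k} (the identity map when V <= T),
    # plus a small seeded jitter.  Anchoring makes the initial term ->
    # topic affinity injective and identical for both documents, so
    # shared terms land in shared topics; a symmetric random start
    # instead maps terms to arbitrary topics, and chance collisions
    # between unrelated terms dominate the pair score.  The coordinate
    # ascent is free to merge or reshape topics away from the anchors
    # when the data support it.
    rng = np.random.Generator(np.random.PCG64(params.seed))
    lam = params.eta + 0.01 * rng.uniform(0.0, 1.0, size=(params.T, n_terms))
    anchor_topics = np.arange(n_terms) % params.T
    lam[anchor_topics, np.arange(n_terms)] += 1.0
    u = np.ones(params.T - 1)
    v = np.full(params.T - 1, params.gamma)

    scale = max(float(sum(d.counts.sum() for d in docs)), 1.0)
    for _ in range(params.iterations):
        elog_phi = digamma(lam) - digamma(lam.sum(axis=1))[:, None]
        elog_sigma = _elog_sticks(u, v, params.T)

        lam_new = np.full((params.T, n_terms), params.eta)
        topic_usage = np.zeros(params.T)
        for doc in docs:
            weighted = _doc_sweep(doc, elog_phi, elog_sigma, params)
            lam_new[:, doc.idx] += doc.zeta.T @ weighted.T
            topic_usage += doc.zeta.sum(axis=0)
        converged = np.max(np.abs(lam_new - lam)) <= params.tol * scale
        lam = lam_new
        u, v = _stick_posteriors(topic_usage, params.gamma)
        if converged:
            break

    elog_phi = digamma(lam) - digamma(lam.sum(axis=1))[:, None]
    elog_sigma = _elog_sticks(u, v, params.T)
    return HdpModelState(
        topic_term_weights=lam,
        elog_phi=elog_phi,
        elog_sigma=elog_sigma,
        n_terms=n_terms,
        params=params,
    )


def topic_distribution(model: HdpModelState, doc: PseudoBow) -> TopicDistribution:
    """Infer the topic-proportion vector of ``doc`` under the fitted model.

    Document-side factors are re-inferred from a deterministic
    initialization against the frozen global state, so the result is a
    pure function of (model, doc): querying twice gives identical vectors,
    and identical documents get identical distributions.
    """
    params = model.params
    state = _DocState(*_validate_doc(doc, model.n_terms), params)
    scale = max(float(state.counts.sum()), 1.0)
    for _ in range(params.iterations):
        before = state.weighted
        _doc_sweep(state, model.elog_phi, model.elog_sigma, params)
        if np.max(np.abs(state.weighted - before)) <= params.tol * scale:
            break

    e_pi = _expected_sticks(state.a, state.b, params.K)  # (K,)
    theta = e_pi @ state.zeta  # (T,)
    theta = np.maximum(theta, 0.0)
    return TopicDistribution(theta / theta.sum())
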