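"""Quantization: brute-force oracle equivalence, merging, pair corpora."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from embedhdp import (
    ConfigurationError,
    DegenerateDocumentError,
    PseudoBow,
    QuantizeConfig,
    TermDictionary,
    build_pair_corpus,
    load_lexicon,
    make_hash_backend,
    quantize_vector,
    sentence_bow,
    tokenize,
)


def brute_force_quantize(v, L, scale, negative_handling="clip"):
    """Independent oracle: full sort over all components by (-value, index)."""
    w = [abs(x) if negative_handling == "absolute" else max(x, 0.0) for x in v]
    order = sorted(range(len(v)), key=lambda i: (-w[i], i))[:L]
    return {i: scale * w[i] for i in order if w[i] > 0}


class TestQuantizeVector:
    def test_hand_example_clip(self):
        bow = quantize_vector(np.array([0.02, -0.5, 0.01]), QuantizeConfig(L=2))
        assert bow.as_dict() == pytest.approx({0: 2.0, 2: 1.0})

    def test_hand_example_absolute(self):
        bow = quantize_vector(
            np.array([0.02, -0.5, 0.01]),
            QuantizeConfig(L=2, negative_handling="absolute"),
        )
        assert bow.as_dict() == pytest.approx({0: 2.0, 1: 50.0})

    def test_all_zero_vector_gives_empty_bow(self):
        assert len(quantize_vector(np.zeros(8))) == 0

    def test_one_hot(self):
        v = np.zeros(8)
        v[5] = 0.07
        assert quantize_vector(v).as_dict() == pytest.approx({5: 7.0})

    def test_ties_break_to_lower_dimension(self):
        v = np.array([0.5, 0.5, 0.5])
        bow = quantize_vector(v, QuantizeConfig(L=2))
        assert sorted(bow.as_dict()) == [0, 1]

    def test_oracle_equivalence_on_random_vectors(self):
        rng = np.random.default_rng(7)
        cfg = QuantizeConfig(L=10)
        for _ in range(1000):
            v = rng.standard_normal(rng.integers(2, 40))
            got = quantize_vector(v, cfg).as_dict()
            want = brute_force_quantize(v, cfg.L, cfg.scale)
            assert got == pytest.approx(want)

    @given(st.integers(1, 12), st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_increasing_L_is_prefix_monotone(self, L, seed):
        v = np.random.default_rng(seed).standard_normal(16)
        small = quantize_vector(v, QuantizeConfig(L=L)).as_dict()
        large = quantize_vector(v, QuantizeConfig(L=L + 3)).as_dict()
        assert set(small) <= set(large)
        for k, w in small.items():
            assert large[k] == w

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_weights_strictly_positive(self, seed):
        v = np.random.default_rng(seed).standard_normal(24)
        for handling in ("clip", "absolute"):
            bow = quantize_vector(v, QuantizeConfig(negative_handling=handling))
            assert all(w > 0 for _, w in bow.entries)
            assert len(bow) <= 10


class TestSentenceBow:
    def test_single_token_equals_quantize_vector(self, stub16):
        toks = tokenize("alpha")
        bow = sentence_bow(toks, stub16)
        direct = quantize_vector(stub16.embed("alpha"))
        assert bow.as_dict() == pytest.approx(direct.as_dict())

    def test_repeated_token_doubles_weights(self, stub16):
        single = sentence_bow(tokenize("w"), stub16).as_dict()
        double = sentence_bow(tokenize("w w"), stub16).as_dict()
        assert double == pytest.approx({k: 2 * v for k, v in single.items()})

    def test_three_token_merge_matches_hand_sum(self):
        backend = make_hash_backend(dim=16, seed=7)
        cfg = QuantizeConfig(L=3)
        acc = {}
        for tok in ("alpha", "beta", "gamma"):
            for k, w in brute_force_quantize(backend.embed(tok), 3, 100.0).items():
                acc[k] = acc.get(k, 0.0) + w
        bow = sentence_bow(tokenize("alpha beta gamma"), backend, cfg)
        assert bow.as_dict() == pytest.approx(acc)


class _ZeroBackend:
    dim = 4
    name = "zero"

    def embed(self, token):
        return np.zeros(4)


class TestPairCorpus:
    def test_identical_sentences_identical_documents(self, stub16):
        s = tokenize("コルセット を 作る")
        _, (c1, c2) = build_pair_corpus(s, s, stub16)
        assert c1 == c2

    def test_dictionary_is_union_without_lexicon(self, stub16):
        s1, s2 = tokenize("a b c"), tokenize("c d")
        dictionary, (c1, c2) = build_pair_corpus(s1, s2, stub16)
        used = {t for t, _ in c1.entries} | {t for t, _ in c2.entries}
        assert used == set(range(len(dictionary)))

    def test_dictionary_size_matches_brute_force_union(self):
        backend = make_hash_backend(dim=16, seed=7)
        s1, s2 = tokenize("alpha beta"), tokenize("beta gamma")
        dims = set()
        for tok in ("alpha", "beta", "gamma"):
            dims |= set(brute_force_quantize(backend.embed(tok), 10, 100.0))
        dictionary, _ = build_pair_corpus(s1, s2, backend)
        assert len(dictionary) == len(dims)

    def test_lexicon_augments_dictionary(self, stub16, tmp_path):
        lex = tmp_path / "lex.txt"
        lex.write_text("感染\n# comment line\n点眼薬\n", encoding="utf-8")
        terms = load_lexicon(lex)
        assert terms == ["感染", "点眼薬"]
        s1, s2 = tokenize("a"), tokenize("b")
        d_plain, _ = build_pair_corpus(s1, s2, stub16)
        d_aug, docs = build_pair_corpus(s1, s2, stub16, lexicon=terms)
        assert len(d_aug) >= len(d_plain)
        # documents still only reference ids inside the dictionary
        for doc in docs:
            assert all(0 <= t < len(d_aug) for t, _ in doc.entries)

    def test_degenerate_document_raises(self):
        with pytest.raises(DegenerateDocumentError):
            sentence_bow(tokenize("x"), _ZeroBackend())


class TestTypes:
    def test_duplicate_term_ids_rejected(self):
        with pytest.raises(Exception):
            PseudoBow(((1, 2.0), (1, 3.0)))

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(Exception):
            PseudoBow(((0, 0.0),))

    def test_term_dictionary_bijective_contiguous(self):
        d = TermDictionary.from_terms([9, 3, 3, 7])
        assert d.term_of == (3, 7, 9)
        assert [d.id_of[t] for t in d.term_of] == [0, 1, 2]

    @pytest.mark.parametrize("kwargs", [{"L": 0}, {"scale": 0.0}, {"negative_handling": "drop"}])
    def test_bad_config_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            QuantizeConfig(**kwargs)
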