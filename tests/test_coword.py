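import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from infodemic import (
    PairMatrix,
    cooccurrence_matrix,
    degree_centrality,
    document_frequencies,
    ochiai_transform,
    select_high_freq,
    term_frequencies,
    tokenize,
)
from infodemic.coword import CowordError, build_coword


def brute_force_cooccurrence(titles, terms):
    """Independent oracle: explicit double loop over titles and term pairs."""
    n = len(terms)
    counts = np.zeros((n, n))
    token_sets = [set(tokenize(t)) for t in titles]
    for i, a in enumerate(terms):
        for j, b in enumerate(terms):
            if i != j:
                counts[i, j] = sum(1 for toks in token_sets if a in toks and b in toks)
    return counts


class TestTokenize:
    def test_repeated_tokens_kept(self):
        assert tokenize("flu alert flu") == ["flu", "alert", "flu"]

    def test_stoplist_filters(self):
        assert tokenize("flu alert flu", stoplist=["alert"]) == ["flu", "flu"]

    def test_empty_title_gives_empty_list(self):
        assert tokenize("") == []
        assert tokenize("  !! ") == []

    def test_plugin_tokenizer_contract(self):
        """Any callable title -> tokens slots in; its output is still
        canonicalized and stoplist-filtered."""
        bigrams = lambda s: [s[i : i + 2] for i in range(0, len(s), 2)]
        assert tokenize("abcd", tokenizer=bigrams) == ["ab", "cd"]
        assert tokenize("ABCD", stoplist=["cd"], tokenizer=bigrams) == ["ab"]


class TestFrequencies:
    def test_hand_counted(self):
        freqs = term_frequencies(["a b", "a c"])
        assert freqs.to_dict() == {"a": 2, "b": 1, "c": 1}
        assert freqs.index[0] == "a"

    def test_occurrence_not_document_frequency(self):
        freqs = term_frequencies(["flu flu", "flu"])
        assert freqs["flu"] == 3
        assert document_frequencies(["flu flu", "flu"])["flu"] == 2

    def test_empty_corpus(self):
        assert term_frequencies([]).empty

    def test_zipf_exponent_recovered_from_generated_fillers(self):
        """Rank-frequency slope of a Zipf(1.1) vocabulary sample matches the
        planted exponent within 0.1 on the top ranks."""
        rng = np.random.default_rng(4)
        size, s = 300, 1.1
        p = np.arange(1, size + 1, dtype=float) ** (-s)
        p /= p.sum()
        draws = rng.choice(size, size=40_000, p=p)
        counts = np.bincount(draws, minlength=size)
        ranks = np.arange(1, size + 1)
        top = slice(0, 50)
        fit = stats.linregress(np.log(ranks[top]), np.log(np.sort(counts)[::-1][top]))
        assert fit.slope == pytest.approx(-s, abs=0.1)


class TestSelectHighFreq:
    def test_strictly_greater_than_floor(self):
        import pandas as pd

        table = pd.Series({"a": 100, "b": 61, "c": 60, "d": 59})
        assert select_high_freq(table, min_freq=60) == ["a", "b"]

    def test_zero_floor_keeps_everything(self):
        import pandas as pd

        table = pd.Series({"a": 3, "b": 1})
        assert set(select_high_freq(table, min_freq=0, top_k=10)) == {"a", "b"}

    def test_truncation_and_tie_break(self):
        import pandas as pd

        table = pd.Series({f"t{i:03d}": 10 for i in range(150)})
        kept = select_high_freq(table, min_freq=0, top_k=100)
        assert len(kept) == 100
        assert kept == sorted(kept)  # lexicographic among tied counts

    def test_bad_top_k(self):
        import pandas as pd

        with pytest.raises(CowordError):
            select_high_freq(pd.Series({"a": 1}), top_k=0)


class TestCooccurrence:
    def test_enumerated_counts(self):
        m = cooccurrence_matrix(["a b", "a b", "a c"], ["a", "b", "c"])
        assert m.values[0, 1] == 2  # a-b
        assert m.values[0, 2] == 1  # a-c
        assert m.values[1, 2] == 0  # b-c

    def test_presence_based_within_title(self):
        # repeated token within one title still counts once per pair
        m = cooccurrence_matrix(["a a b"], ["a", "b"])
        assert m.values[0, 1] == 1

    def test_disjoint_titles_give_zero_matrix(self):
        m = cooccurrence_matrix(["a b", "c d"], ["a", "c"])
        assert not m.values.any()

    def test_matches_brute_force_on_random_titles(self):
        rng = np.random.default_rng(7)
        vocab = [f"v{i}" for i in range(20)]
        titles = [
            " ".join(rng.choice(vocab, size=rng.integers(2, 8)))
            for _ in range(200)
        ]
        terms = vocab[:10]
        fast = cooccurrence_matrix(titles, terms)
        assert np.array_equal(fast.values, brute_force_cooccurrence(titles, terms))

    def test_empty_term_list_rejected(self):
        with pytest.raises(CowordError):
            cooccurrence_matrix(["a b"], [])


class TestOchiai:
    def test_hand_computed_value(self):
        counts = PairMatrix(labels=("A", "B"), values=np.array([[0.0, 10.0], [10.0, 0.0]]))
        result = ochiai_transform(counts, {"A": 100, "B": 25})
        assert result.ochiai.values[0, 1] == pytest.approx(10 / np.sqrt(2500))  # 0.2

    def test_three_title_example(self):
        titles = ["a b", "a b", "a c"]
        freqs = term_frequencies(titles)
        counts = cooccurrence_matrix(titles, ["a", "b"])
        y = ochiai_transform(counts, freqs).ochiai.values[0, 1]
        assert y == pytest.approx(2 / np.sqrt(6), abs=1e-9)  # X_ab=2, X_a=3, X_b=2

    def test_zero_cooccurrence_maps_to_zero(self):
        counts = PairMatrix(labels=("A", "B"), values=np.zeros((2, 2)))
        assert ochiai_transform(counts, {"A": 5, "B": 5}).ochiai.values[0, 1] == 0.0

    def test_zero_frequency_rejected(self):
        counts = PairMatrix(labels=("A", "B"), values=np.zeros((2, 2)))
        with pytest.raises(CowordError):
            ochiai_transform(counts, {"A": 0, "B": 5})

    def test_self_similarity_is_one(self):
        """Extending the diagonal with X_AA = X_A yields y = 1."""
        titles = ["a b", "a b", "a c"]
        freqs = term_frequencies(titles)
        counts = cooccurrence_matrix(titles, ["a", "b"])
        f = np.array([freqs["a"], freqs["b"]], dtype=float)
        raw = counts.values.copy()
        np.fill_diagonal(raw, f)
        y = raw / np.sqrt(np.outer(f, f))
        assert np.allclose(np.diagonal(y), 1.0)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_values_stay_in_unit_interval_on_random_corpora(self, seed):
        """Presence-based X_AB never exceeds sqrt(X_A X_B) under either
        marginal convention, so all Ochiai values live in [0, 1]."""
        rng = np.random.default_rng(seed)
        vocab = [f"v{i}" for i in range(8)]
        titles = [
            " ".join(rng.choice(vocab, size=rng.integers(1, 6)))
            for _ in range(30)
        ]
        freqs = term_frequencies(titles)
        terms = list(freqs.index[: min(5, len(freqs))])
        counts = cooccurrence_matrix(titles, terms)
        for marginals in (freqs, document_frequencies(titles)):
            y = ochiai_transform(counts, marginals).ochiai.values
            assert np.all(y >= 0) and np.all(y <= 1 + 1e-12)


class TestCentrality:
    def _star(self, n=5):
        values = np.zeros((n, n))
        values[0, 1:] = values[1:, 0] = 0.5
        return PairMatrix(labels=tuple(f"t{i}" for i in range(n)), values=values)

    def test_star_center_has_binary_centrality_one(self):
        cent = degree_centrality(self._star(), mode="binary")
        assert cent["t0"] == pytest.approx(1.0)
        assert cent["t1"] == pytest.approx(1 / 4)

    def test_isolated_term_has_zero_centrality(self):
        values = np.zeros((3, 3))
        values[0, 1] = values[1, 0] = 1.0
        cent = degree_centrality(PairMatrix(labels=("a", "b", "c"), values=values))
        assert cent["c"] == 0.0

    def test_valued_mode_is_row_sum(self):
        cent = degree_centrality(self._star(), mode="valued")
        assert cent["t0"] == pytest.approx(2.0)

    def test_planted_hub_term_dominates(self):
        """A term planted in every title gets the maximum centrality."""
        rng = np.random.default_rng(9)
        vocab = [f"v{i}" for i in range(10)]
        titles = [
            "hub " + " ".join(rng.choice(vocab, size=3)) for _ in range(100)
        ]
        freqs, coword = build_coword(titles, min_freq=0, top_k=11)
        cent = degree_centrality(coword.ochiai, mode="binary")
        assert cent.index[0] == "hub"


class TestBuildCoword:
    def test_full_pass_shapes_and_bounds(self, small_config):
        from infodemic import generate_corpus

        corpus, _ = generate_corpus(small_config)
        freqs, coword = build_coword(corpus, min_freq=10, top_k=50)
        assert 0 < len(coword.terms) <= 50
        assert np.all(coword.ochiai.values <= 1.0 + 1e-12)
        assert np.array_equal(coword.counts.values, coword.counts.values.T)

    def test_unknown_marginals_rejected(self):
        with pytest.raises(CowordError):
            build_coword(["a b"], min_freq=0, marginals="nope")
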