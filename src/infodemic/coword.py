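"""Co-word analysis of article titles.

Titles are tokenized (whitespace by default, any segmenter pluggable),
stopword-filtered, and counted; terms above a frequency floor form a
co-occurrence network in which the tie between terms A and B is the number of
titles containing both.  The raw counts are rescaled by the Ochiai
coefficient

    y = X_AB / sqrt(X_A * X_B),

the co-occurrence count normalized by the geometric mean of the marginal
frequencies, which maps ties into [0, 1] and removes the frequency gap
between common and rare terms.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .corpus import Corpus
from .independence import NetworkError, PairMatrix, normalize_title

Tokenizer = Callable[[str], Sequence[str]]


class CowordError(ValueError):
    """Raised for invalid co-word parameters."""


def tokenize(
    title: str,
    stoplist: Iterable[str] = (),
    tokenizer: Tokenizer | None = None,
) -> list[str]:
    """Split a title into canonical, stoplist-filtered tokens.

    The default tokenizer splits the normalized title on whitespace; pass any
    callable taking the raw title and returning raw tokens (e.g. a Chinese
    segmenter) to replace it.  Tokens are casefolded either way.
    Part-of-speech selection, where wanted, belongs inside the tokenizer.
    """
    stop = {str(w).casefold() for w in stoplist}
    if tokenizer is None:
        raw = normalize_title(title).split()
    else:
        raw = [normalize_title(t) for t in tokenizer(str(title))]
    return [t for t in raw if t and t not in stop]


def _titles_of(source: Corpus | Iterable[str]) -> list[str]:
    if isinstance(source, Corpus):
        return [r.title for r in source.records]
    return [str(t) for t in source]


def term_frequencies(
    source: Corpus | Iterable[str],
    stoplist: Iterable[str] = (),
    tokenizer: Tokenizer | None = None,
) -> pd.Series:
    """Total occurrence count of every token across all titles, descending.

    Counts occurrences, not document frequency: a token appearing twice in
    one title contributes 2.
    """
    counts: Counter[str] = Counter()
    for title in _titles_of(source):
        counts.update(tokenize(title, stoplist, tokenizer))
    series = pd.Series(counts, dtype=int, name="frequency")
    # descending count, lexicographic within ties
    return series.sort_index(kind="stable").sort_values(ascending=False, kind="stable")


def document_frequencies(
    source: Corpus | Iterable[str],
    stoplist: Iterable[str] = (),
    tokenizer: Tokenizer | None = None,
) -> pd.Series:
    """Number of titles containing each token at least once, descending."""
    counts: Counter[str] = Counter()
    for title in _titles_of(source):
        counts.update(set(tokenize(title, stoplist, tokenizer)))
    series = pd.Series(counts, dtype=int, name="document_frequency")
    return series.sort_index(kind="stable").sort_values(ascending=False, kind="stable")


def select_high_freq(table: pd.Series, min_freq: int = 60, top_k: int = 100) -> list[str]:
    """High-frequency terms: count strictly greater than ``min_freq``, kept in
    descending count order (ties broken lexicographically), truncated to
    ``top_k``."""
    if top_k < 1:
        raise CowordError(f"top_k must be >= 1, got {top_k}")
    if table.empty:
        raise CowordError("empty frequency table")
    qualifying = table[table > min_freq]
    ordered = sorted(qualifying.items(), key=lambda kv: (-kv[1], kv[0]))
    return [term for term, _ in ordered[:top_k]]


def cooccurrence_matrix(
    source: Corpus | Iterable[str],
    terms: Sequence[str],
    stoplist: Iterable[str] = (),
    tokenizer: Tokenizer | None = None,
) -> PairMatrix:
    """Presence-based co-occurrence counts X_AB over the selected terms.

    X_AB = number of titles in which both A and B appear (each title
    contributes at most 1 to a pair).  Symmetric, zero diagonal.
    """
    terms = list(terms)
    if not terms:
        raise CowordError("empty term list")
    index = {t: i for i, t in enumerate(terms)}
    incidence = np.zeros((len(_titles_of(source)), len(terms)), dtype=np.int64)
    for row, title in enumerate(_titles_of(source)):
        for tok in set(tokenize(title, stoplist, tokenizer)):
            if tok in index:
                incidence[row, index[tok]] = 1
    counts = incidence.T @ incidence
    np.fill_diagonal(counts, 0)
    return PairMatrix(labels=tuple(terms), values=counts.astype(float))


@dataclasses.dataclass(frozen=True)
class CowordMatrix:
    """Raw co-occurrence counts plus their Ochiai-rescaled values in [0, 1]."""

    counts: PairMatrix
    ochiai: PairMatrix

    @property
    def terms(self) -> tuple[str, ...]:
        return self.counts.labels


def ochiai_transform(counts: PairMatrix, frequencies: Mapping[str, int] | pd.Series) -> CowordMatrix:
    """Rescale raw co-occurrence counts by y = X_AB / sqrt(X_A * X_B).

    ``frequencies`` supplies the marginals X_A: pass total occurrence counts
    (the conventional choice here) or document frequencies — under either,
    presence-based X_AB cannot exceed sqrt(X_A * X_B), so y stays in [0, 1].
    """
    freqs = np.array([float(frequencies[t]) for t in counts.labels])
    if np.any(freqs <= 0):
        bad = [t for t, f in zip(counts.labels, freqs) if f <= 0]
        raise CowordError(f"zero frequency for selected term(s): {bad}")
    denom = np.sqrt(np.outer(freqs, freqs))
    y = counts.values / denom
    return CowordMatrix(counts=counts, ochiai=PairMatrix(labels=counts.labels, values=y))


def degree_centrality(matrix: PairMatrix, mode: str = "binary") -> pd.Series:
    """Point degree centrality per term, descending.

    ``binary`` — share of possible neighbors with a nonzero tie (computed on
    the dichotomized graph via networkx); ``valued`` — row sum of tie values.
    """
    if matrix.n < 2:
        raise NetworkError("centrality needs at least 2 nodes")
    if mode == "binary":
        graph = nx.from_numpy_array(matrix.values > 0)
        cent = nx.degree_centrality(graph)
        series = pd.Series({matrix.labels[i]: c for i, c in cent.items()}, name="centrality")
    elif mode == "valued":
        series = pd.Series(matrix.values.sum(axis=1), index=list(matrix.labels), name="centrality")
    else:
        raise CowordError(f"unknown centrality mode {mode!r}")
    return series.sort_values(ascending=False, kind="stable")


def build_coword(
    source: Corpus | Iterable[str],
    stoplist: Iterable[str] = (),
    min_freq: int = 60,
    top_k: int = 100,
    marginals: str = "occurrence",
    tokenizer: Tokenizer | None = None,
) -> tuple[pd.Series, CowordMatrix]:
    """Full co-word pass: frequencies -> selection -> counts -> Ochiai.

    ``marginals`` picks the X_A convention for the Ochiai denominator:
    ``occurrence`` (total token counts, default) or ``presence`` (document
    frequencies).  Returns the frequency table and the coword matrices.
    """
    freqs = term_frequencies(source, stoplist, tokenizer)
    terms = select_high_freq(freqs, min_freq=min_freq, top_k=top_k)
    counts = cooccurrence_matrix(source, terms, stoplist, tokenizer)
    if marginals == "occurrence":
        marg = freqs
    elif marginals == "presence":
        marg = document_frequencies(source, stoplist, tokenizer)
    else:
        raise CowordError(f"unknown marginals convention {marginals!r}")
    return freqs, ochiai_transform(counts, marg)
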