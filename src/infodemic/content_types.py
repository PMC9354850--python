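"""Content-type taxonomy, lexicon classifier, and type-distribution tables.

Posts about a public-health emergency fall into six categories: (1) epidemic
overview release, (2) prevention and control measures, (3) science and
disinformation, (4) front-line assistance stories, (5) epidemic impact
(reopening etc.), and (6) negative impact (misconduct).  Human coders assign
these labels in practice; here a transparent keyword-lexicon classifier
stands in, which is exact on synthetic corpora built from disjoint lexicons
and auditable on real ones.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from collections import Counter
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .corpus import Corpus, CorpusError, TweetRecord

CONTENT_TYPES: dict[int, str] = {
    1: "epidemic overview release",
    2: "epidemic prevention and control measures",
    3: "science and disinformation",
    4: "epidemic line assistance stories",
    5: "epidemic impact",
    6: "negative impact",
}

N_TYPES = len(CONTENT_TYPES)

#: Default keyword lists, pairwise disjoint so that generated corpora are
#: exactly recoverable.  Real corpora should supply a curated lexicon.
DEFAULT_KEYWORDS: dict[int, tuple[str, ...]] = {
    1: ("cases", "confirmed", "briefing", "tally", "update", "daily", "province", "report"),
    2: ("policy", "lockdown", "quarantine", "measures", "notice", "checkpoint", "directive", "inspection"),
    3: ("virus", "symptoms", "mask", "rumor", "myth", "prevention", "hygiene", "knowledge"),
    4: ("volunteer", "medics", "frontline", "tribute", "donation", "rescue", "heroes", "support"),
    5: ("reopening", "school", "resumption", "economy", "travel", "unseal", "recovery", "commute"),
    6: ("corruption", "concealment", "misconduct", "penalty", "violation", "deception", "hoarding", "negligence"),
}


class ClassificationError(ValueError):
    """Raised for invalid lexicons or unlabeled corpora."""


@dataclasses.dataclass(frozen=True)
class TypeLexicon:
    """Keyword lexicon for the six content types.

    ``priority`` breaks ties (earlier wins); ``fallback`` is the label for
    titles with zero keyword hits — either ``None`` (unclassified) or a
    default type code.
    """

    keywords: Mapping[int, frozenset[str]]
    priority: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    fallback: int | None = None

    def __post_init__(self) -> None:
        if set(self.keywords) != set(CONTENT_TYPES):
            raise ClassificationError("lexicon must cover exactly the six type codes 1..6")
        if sorted(self.priority) != list(CONTENT_TYPES):
            raise ClassificationError("priority must be a permutation of 1..6")
        if any(not words for words in self.keywords.values()):
            raise ClassificationError("every type needs at least one keyword")
        for code, words in self.keywords.items():
            for w in words:
                if w != w.strip().casefold():
                    raise ClassificationError(f"keyword {w!r} (type {code}) is not normalized")
        if self.fallback is not None and self.fallback not in CONTENT_TYPES:
            raise ClassificationError(f"fallback must be None or 1..6, got {self.fallback!r}")

    def is_disjoint(self) -> bool:
        seen: set[str] = set()
        for words in self.keywords.values():
            if seen & words:
                return False
            seen |= words
        return True

    @classmethod
    def from_yaml(cls, path) -> "TypeLexicon":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        keywords = {int(k): frozenset(str(w).casefold() for w in v) for k, v in data["keywords"].items()}
        priority = tuple(data.get("priority", (1, 2, 3, 4, 5, 6)))
        fallback = data.get("fallback")
        return cls(keywords=keywords, priority=priority, fallback=fallback)


def default_lexicon(fallback: int | None = None) -> TypeLexicon:
    return TypeLexicon(
        keywords={k: frozenset(v) for k, v in DEFAULT_KEYWORDS.items()},
        fallback=fallback,
    )


def classify_tweet(title: str, lexicon: TypeLexicon, tokenizer=None) -> int | None:
    """Label one title: the type with the most keyword hits (with multiplicity).

    Ties go to the earlier type in ``lexicon.priority``; zero hits return the
    lexicon's fallback.  ``tokenizer`` overrides the default
    whitespace/punctuation tokenization (see :func:`infodemic.coword.tokenize`).
    """
    from .coword import tokenize  # local import to avoid a cycle

    tokens = tokenize(title, tokenizer=tokenizer)
    counts = Counter(tokens)
    hits = {
        code: sum(n for tok, n in counts.items() if tok in words)
        for code, words in lexicon.keywords.items()
    }
    best = max(hits.values())
    if best == 0:
        return lexicon.fallback
    for code in lexicon.priority:
        if hits[code] == best:
            return code
    raise AssertionError("unreachable")  # pragma: no cover


def classify_corpus(corpus: Corpus, lexicon: TypeLexicon, tokenizer=None) -> Corpus:
    """Return a copy of the corpus with ``content_type`` set from the lexicon."""
    records = tuple(
        dataclasses.replace(r, content_type=classify_tweet(r.title, lexicon, tokenizer))
        for r in corpus.records
    )
    return Corpus(records=records, collection_date=corpus.collection_date)


def type_counts(corpus: Corpus) -> pd.Series:
    """Posts per content type (codes 1..6), zero-filled; errors on unlabeled."""
    labels = [r.content_type for r in corpus.records]
    if any(label is None for label in labels):
        n = sum(label is None for label in labels)
        raise ClassificationError(f"{n} record(s) are unlabeled; classify the corpus first")
    counts = pd.Series(Counter(labels))
    return counts.reindex(list(CONTENT_TYPES), fill_value=0).astype(int)


def type_distribution(corpus: Corpus, empty_accounts: str = "error") -> pd.DataFrame:
    """Per-account percentage of each content type (rows sum to 100).

    ``empty_accounts`` controls accounts with zero posts when an explicit
    account list is attached: ``"error"`` raises, ``"zero"`` emits a zero row.
    (Accounts are derived from the records, so empty rows only arise via
    ``"zero"`` handling of an all-unlabeled slice.)
    """
    if empty_accounts not in ("error", "zero"):
        raise ClassificationError(f"empty_accounts must be 'error' or 'zero', got {empty_accounts!r}")
    frame = corpus.to_frame()
    if frame.empty:
        raise ClassificationError("empty corpus")
    if frame["content_type"].isna().any():
        n = int(frame["content_type"].isna().sum())
        raise ClassificationError(f"{n} record(s) are unlabeled; classify the corpus first")
    counts = (
        frame.groupby(["account_id", "content_type"]).size().unstack(fill_value=0)
        .reindex(columns=list(CONTENT_TYPES), fill_value=0)
    )
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        empties = list(totals.index[totals == 0])
        if empty_accounts == "error":
            raise ClassificationError(f"account(s) with zero posts: {empties}")
        pct = counts.astype(float)
        nonzero = totals > 0
        pct.loc[nonzero] = counts.loc[nonzero].div(totals[nonzero], axis=0) * 100.0
        return pct
    return counts.div(totals, axis=0) * 100.0


def weekly_type_proportions(corpus: Corpus, anchor_date: dt.date | None = None) -> pd.DataFrame:
    """Content-type proportions per 7-day week (rows sum to 1).

    Weeks are anchored at ``anchor_date`` (default: earliest posting date);
    the final week may be partial.  Posts before the anchor are an error.
    """
    frame = corpus.to_frame()
    if frame.empty:
        raise ClassificationError("empty corpus")
    if frame["content_type"].isna().any():
        raise ClassificationError("unlabeled record(s); classify the corpus first")
    dates = frame["posted_at"].dt.date
    if anchor_date is None:
        anchor_date = dates.min()
    offsets = pd.Series([(d - anchor_date).days for d in dates], index=frame.index)
    if (offsets < 0).any():
        raise ClassificationError(f"record(s) posted before anchor date {anchor_date}")
    frame = frame.assign(week=offsets // 7 + 1)
    counts = (
        frame.groupby(["week", "content_type"]).size().unstack(fill_value=0)
        .reindex(columns=list(CONTENT_TYPES), fill_value=0)
    )
    return counts.div(counts.sum(axis=1), axis=0)
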