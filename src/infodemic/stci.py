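"""Single-post communication index (STCI) scoring and engagement summaries.

The STCI is a single-article variant of the WeChat Communication Index
family.  For a post with cumulative reads R, cumulative likes Z, and age d
days (posting date through collection date, both counted, so d >= 1):

    STCI = 10 * [ 0.6 * (0.2*ln(R/d + 1) + 0.8*ln(R + 1))
                + 0.4 * (0.2*ln(10*Z/d + 1) + 0.8*ln(10*Z + 1)) ]^2

Reads carry 60% of the weight and likes 40%; within each, the per-day rate
carries 20% against 80% for the cumulative total; likes are scaled by 10 to
put them on a comparable magnitude to reads.  The log-blend is squared and
scaled by 10, which places strongly circulated posts (R ~ 10^4..10^5) in the
900-1,100 range.  The index is zero iff R = Z = 0, strictly increasing in R
and Z, and non-increasing in d.

All four rendering choices for the index live in :func:`compute_stci` only.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from typing import Iterable

import numpy as np
import pandas as pd

from .corpus import Corpus, CorpusError, TweetRecord

W_READS = 0.6
W_LIKES = 0.4
W_DAILY = 0.2
W_TOTAL = 0.8
LIKE_SCALE = 10.0
OUTER_SCALE = 10.0


class ScoringError(ValueError):
    """Raised for invalid STCI inputs."""


@dataclasses.dataclass(frozen=True)
class STCIResult:
    """Score decomposition for one post."""

    account_id: str
    title: str
    reads: int
    likes: int
    days: int
    read_censored: bool
    content_type: int | None
    score: float


def compute_stci(reads, likes, days):
    """Evaluate the STCI.  Accepts scalars or numpy arrays (broadcast).

    ``days`` must be >= 1 (the inclusive post-to-collection day count);
    ``reads`` and ``likes`` must be nonnegative.
    """
    R = np.asarray(reads, dtype=float)
    Z = np.asarray(likes, dtype=float)
    d = np.asarray(days, dtype=float)
    if np.any(d < 1):
        raise ScoringError("days must be >= 1")
    if np.any(R < 0) or np.any(Z < 0):
        raise ScoringError("reads and likes must be nonnegative")
    read_blend = W_DAILY * np.log(R / d + 1.0) + W_TOTAL * np.log(R + 1.0)
    like_blend = W_DAILY * np.log(LIKE_SCALE * Z / d + 1.0) + W_TOTAL * np.log(LIKE_SCALE * Z + 1.0)
    score = OUTER_SCALE * (W_READS * read_blend + W_LIKES * like_blend) ** 2
    if score.ndim == 0:
        return float(score)
    return score


def post_age_days(posted: dt.date, collection_date: dt.date) -> int:
    """Inclusive day count from posting date to collection date (>= 1)."""
    diff = (collection_date - posted).days
    if diff < 0:
        raise ScoringError(
            f"posting date {posted} is after collection date {collection_date}"
        )
    return diff + 1


def score_record(record: TweetRecord, collection_date: dt.date) -> STCIResult:
    """Score one post; censored reads are scored at the cap (a lower bound)."""
    d = post_age_days(record.posted_date, collection_date)
    return STCIResult(
        account_id=record.account_id,
        title=record.title,
        reads=record.read_count,
        likes=record.like_count,
        days=d,
        read_censored=record.read_censored,
        content_type=record.content_type,
        score=compute_stci(record.read_count, record.like_count, d),
    )


def score_corpus(corpus: Corpus) -> pd.DataFrame:
    """STCI for every post, sorted descending by score with a 1-based rank.

    Censored read counts enter at the display cap, so their scores are lower
    bounds; the ``read_censored`` column propagates the flag.  Columns:
    rank, account_id, title, reads, likes, days, read_censored, content_type,
    score.
    """
    if not corpus.records:
        return pd.DataFrame(
            columns=[
                "rank", "account_id", "title", "reads", "likes", "days",
                "read_censored", "content_type", "score",
            ]
        )
    reads = np.array([r.read_count for r in corpus.records], dtype=float)
    likes = np.array([r.like_count for r in corpus.records], dtype=float)
    days = np.array(
        [post_age_days(r.posted_date, corpus.collection_date) for r in corpus.records],
        dtype=float,
    )
    frame = pd.DataFrame(
        {
            "account_id": [r.account_id for r in corpus.records],
            "title": [r.title for r in corpus.records],
            "reads": reads.astype(int),
            "likes": likes.astype(int),
            "days": days.astype(int),
            "read_censored": [r.read_censored for r in corpus.records],
            "content_type": [r.content_type for r in corpus.records],
            "score": compute_stci(reads, likes, days),
        }
    )
    frame = frame.sort_values("score", ascending=False, kind="stable").reset_index(drop=True)
    frame.insert(0, "rank", np.arange(1, len(frame) + 1))
    return frame


def high_stci_filter(scored: pd.DataFrame, threshold: float = 800.0) -> pd.DataFrame:
    """Posts with score strictly greater than ``threshold``, rank order kept."""
    return scored[scored["score"] > threshold].reset_index(drop=True)


def high_stci_breakdown(filtered: pd.DataFrame) -> dict[str, pd.Series]:
    """Per-account and per-type counts among the high-index posts."""
    by_account = filtered.groupby("account_id").size().sort_values(ascending=False, kind="stable")
    by_type = filtered.groupby("content_type").size().sort_values(ascending=False, kind="stable")
    return {"by_account": by_account, "by_type": by_type}


def engagement_summary(corpus: Corpus, reads_over: int = 10_000) -> pd.DataFrame:
    """Per-account engagement: share of posts read more than ``reads_over``
    times (on the displayed, possibly censored value) and mean like count.

    Columns: n_tweets, rate_over_10k, avg_likes; indexed by account.
    """
    if not corpus.records:
        raise CorpusError("empty corpus")
    frame = corpus.to_frame()
    grouped = frame.groupby("account_id")
    summary = pd.DataFrame(
        {
            "n_tweets": grouped.size(),
            "rate_over_10k": grouped["read_count"].apply(
                lambda s: float((s > reads_over).mean())
            ),
            "avg_likes": grouped["like_count"].mean(),
        }
    )
    return summary
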