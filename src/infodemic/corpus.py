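"""Domain types and file I/O for official-account post corpora and case series.

A *corpus* is the set of articles ("tweets") published by a group of
government social-media accounts over a collection window, each carrying the
nine attributes the platform exposes: title, originality flag, read count,
posting time, watch count, like count, comment count, article URL and cover
URL.  The platform displays at most ``read_cap`` reads (100,000 by default);
larger values appear only as the cap, so stored read counts are lower bounds
and carry an explicit ``read_censored`` flag.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

READ_CAP_DEFAULT = 100_000

#: canonical attribute name -> default file column name
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "account_id": "account_id",
    "title": "title",
    "is_original": "is_original",
    "read_count": "read_count",
    "posted_at": "posted_at",
    "watch_count": "watch_count",
    "like_count": "like_count",
    "comment_count": "comment_count",
    "article_url": "article_url",
    "cover_url": "cover_url",
    "content_type": "content_type",
}

_REQUIRED_FIELDS = tuple(k for k in DEFAULT_COLUMN_MAP if k != "content_type")

_TRUE_STRINGS = {"true", "1", "yes", "y"}
_FALSE_STRINGS = {"false", "0", "no", "n", ""}


class CorpusError(ValueError):
    """Raised for malformed corpus or case-series input."""


@dataclasses.dataclass(frozen=True)
class TweetRecord:
    """One published article with its nine platform attributes.

    ``read_count`` is the *displayed* value; when ``read_censored`` is true
    the platform showed only the cap and the stored count equals the cap
    (a lower bound on true reads).  ``content_type`` is an optional label in
    1..6 (see :mod:`infodemic.content_types`).
    """

    account_id: str
    title: str
    is_original: bool
    read_count: int
    read_censored: bool
    posted_at: dt.datetime
    watch_count: int = 0
    like_count: int = 0
    comment_count: int = 0
    article_url: str = ""
    cover_url: str = ""
    content_type: int | None = None

    def __post_init__(self) -> None:
        for field in ("read_count", "watch_count", "like_count", "comment_count"):
            if getattr(self, field) < 0:
                raise CorpusError(f"{field} must be nonnegative, got {getattr(self, field)}")
        if self.content_type is not None and self.content_type not in range(1, 7):
            raise CorpusError(f"content_type must be 1..6, got {self.content_type!r}")

    @property
    def posted_date(self) -> dt.date:
        return self.posted_at.date()

    @property
    def posted_hour(self) -> int:
        return self.posted_at.hour


@dataclasses.dataclass(frozen=True)
class Corpus:
    """An ordered collection of records plus the data-collection date.

    ``collection_date`` is the day engagement figures were read off the
    platform; it anchors the per-post age *d* used by the communication
    index and must not precede any posting date.
    """

    records: tuple[TweetRecord, ...]
    collection_date: dt.date

    def __post_init__(self) -> None:
        if self.records:
            last = max(r.posted_date for r in self.records)
            if self.collection_date < last:
                raise CorpusError(
                    f"collection_date {self.collection_date} precedes latest post {last}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def accounts(self) -> tuple[str, ...]:
        return tuple(sorted({r.account_id for r in self.records}))

    @property
    def date_range(self) -> tuple[dt.date, dt.date]:
        if not self.records:
            raise CorpusError("empty corpus has no date range")
        dates = [r.posted_date for r in self.records]
        return min(dates), max(dates)

    def to_frame(self) -> pd.DataFrame:
        """Tidy DataFrame view, one row per record."""
        return pd.DataFrame(
            {
                "account_id": [r.account_id for r in self.records],
                "title": [r.title for r in self.records],
                "is_original": [r.is_original for r in self.records],
                "read_count": [r.read_count for r in self.records],
                "read_censored": [r.read_censored for r in self.records],
                "posted_at": [r.posted_at for r in self.records],
                "watch_count": [r.watch_count for r in self.records],
                "like_count": [r.like_count for r in self.records],
                "comment_count": [r.comment_count for r in self.records],
                "article_url": [r.article_url for r in self.records],
                "cover_url": [r.cover_url for r in self.records],
                "content_type": [r.content_type for r in self.records],
            }
        )


@dataclasses.dataclass(frozen=True)
class EpidemicSeries:
    """Date-indexed daily counts of newly confirmed cases."""

    dates: tuple[dt.date, ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.dates) != len(self.counts):
            raise CorpusError("dates and counts differ in length")
        for a, b in zip(self.dates, self.dates[1:]):
            if b <= a:
                raise CorpusError(f"dates must be strictly increasing ({a!r} then {b!r})")
        for c in self.counts:
            if c < 0:
                raise CorpusError(f"case count must be nonnegative, got {c}")

    def __len__(self) -> int:
        return len(self.dates)

    def to_series(self) -> pd.Series:
        return pd.Series(list(self.counts), index=list(self.dates), name="new_cases")


def parse_read_count(raw: str | int, cap: int = READ_CAP_DEFAULT) -> tuple[int, bool]:
    """Parse a displayed read count into ``(count, censored)``.

    The platform shows at most ``cap`` reads; a trailing ``+`` or any value at
    or above the cap marks a censored observation, stored as ``(cap, True)``.
    Thousands separators (commas, spaces) are stripped.
    """
    if cap <= 0:
        raise CorpusError(f"cap must be positive, got {cap}")
    text = str(raw).strip()
    censored = text.endswith("+")
    if censored:
        text = text[:-1]
    text = text.replace(",", "").replace(" ", "").replace("_", "")
    if not text.isdigit():
        raise CorpusError(f"unparseable read count {raw!r}")
    count = int(text)
    if censored or count >= cap:
        return cap, True
    return count, False


def _parse_bool(raw: str, row: int) -> bool:
    text = str(raw).strip().lower()
    if text in _TRUE_STRINGS:
        return True
    if text in _FALSE_STRINGS:
        return False
    raise CorpusError(f"row {row}: unparseable boolean {raw!r}")


def _parse_int(raw: str, field: str, row: int) -> int:
    try:
        value = int(str(raw).strip() or 0)
    except ValueError as exc:
        raise CorpusError(f"row {row}: unparseable {field} {raw!r}") from exc
    if value < 0:
        raise CorpusError(f"row {row}: negative {field} {raw!r}")
    return value


def _record_from_row(
    row: Mapping[str, str], row_num: int, colmap: Mapping[str, str], read_cap: int
) -> TweetRecord:
    def get(field: str) -> str:
        return str(row.get(colmap[field], "") or "")

    try:
        posted_at = dt.datetime.fromisoformat(get("posted_at").strip())
    except ValueError as exc:
        raise CorpusError(f"row {row_num}: unparseable timestamp {get('posted_at')!r}") from exc
    try:
        read_count, censored = parse_read_count(get("read_count"), cap=read_cap)
    except CorpusError as exc:
        raise CorpusError(f"row {row_num}: {exc}") from exc
    raw_type = get("content_type").strip()
    content_type = int(float(raw_type)) if raw_type else None
    return TweetRecord(
        account_id=get("account_id"),
        title=get("title"),
        is_original=_parse_bool(get("is_original"), row_num),
        read_count=read_count,
        read_censored=censored,
        posted_at=posted_at,
        watch_count=_parse_int(get("watch_count"), "watch_count", row_num),
        like_count=_parse_int(get("like_count"), "like_count", row_num),
        comment_count=_parse_int(get("comment_count"), "comment_count", row_num),
        article_url=get("article_url"),
        cover_url=get("cover_url"),
        content_type=content_type,
    )


def read_corpus(
    path: str | Path,
    dialect: str = "csv",
    column_map: Mapping[str, str] | None = None,
    collection_date: dt.date | None = None,
    read_cap: int = READ_CAP_DEFAULT,
) -> Corpus:
    """Load and validate a corpus from a CSV or JSON file.

    ``column_map`` maps canonical attribute names to the file's column/key
    names, so corpora with localized headers load without renaming.  If
    ``collection_date`` is omitted it defaults to the latest posting date.
    """
    path = Path(path)
    colmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        colmap.update(column_map)

    if dialect == "csv":
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        if frame.empty and frame.columns.empty:
            raise CorpusError(f"{path}: empty corpus file")
        rows: list[Mapping[str, str]] = frame.to_dict(orient="records")
        present = set(frame.columns)
    elif dialect == "json":
        with open(path, encoding="utf-8") as fh:
            rows = json.load(fh)
        if not isinstance(rows, list):
            raise CorpusError(f"{path}: JSON corpus must be an array of objects")
        if not rows:
            raise CorpusError(f"{path}: empty corpus file")
        present = set(rows[0])
    else:
        raise CorpusError(f"unknown dialect {dialect!r}")

    missing = [f for f in _REQUIRED_FIELDS if colmap[f] not in present]
    if missing:
        raise CorpusError(
            f"{path}: missing required column(s) "
            + ", ".join(f"{colmap[f]!r} (for {f})" for f in missing)
        )

    records = tuple(
        _record_from_row(row, i + 2, colmap, read_cap) for i, row in enumerate(rows)
    )
    if collection_date is None:
        collection_date = max(r.posted_date for r in records)
    return Corpus(records=records, collection_date=collection_date)


def write_corpus(corpus: Corpus, path: str | Path, dialect: str = "csv") -> None:
    """Write a corpus; censored read counts keep their ``<cap>+`` display form.

    Round-trips with :func:`read_corpus` field-for-field.
    """
    path = Path(path)
    rows = []
    for r in corpus.records:
        rows.append(
            {
                "account_id": r.account_id,
                "title": r.title,
                "is_original": str(r.is_original).lower(),
                "read_count": f"{r.read_count}+" if r.read_censored else str(r.read_count),
                "posted_at": r.posted_at.isoformat(),
                "watch_count": r.watch_count,
                "like_count": r.like_count,
                "comment_count": r.comment_count,
                "article_url": r.article_url,
                "cover_url": r.cover_url,
                "content_type": "" if r.content_type is None else r.content_type,
            }
        )
    if dialect == "csv":
        pd.DataFrame(rows, columns=list(DEFAULT_COLUMN_MAP.values())).to_csv(
            path, index=False
        )
    elif dialect == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(rows, fh, ensure_ascii=False, indent=1)
    else:
        raise CorpusError(f"unknown dialect {dialect!r}")


def read_case_series(path: str | Path) -> EpidemicSeries:
    """Load a two-column ``date,new_cases`` CSV into a sorted case series."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("date", "new_cases"):
        if col not in frame.columns:
            raise CorpusError(f"{path}: missing required column {col!r}")
    pairs = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            date = dt.date.fromisoformat(str(row.date).strip())
        except ValueError as exc:
            raise CorpusError(f"row {i}: unparseable date {row.date!r}") from exc
        count = _parse_int(row.new_cases, "new_cases", i)
        pairs.append((date, count))
    pairs.sort(key=lambda p: p[0])
    dates = tuple(p[0] for p in pairs)
    if len(set(dates)) != len(dates):
        dupes = sorted({d for d in dates if dates.count(d) > 1})
        raise CorpusError(f"duplicate date(s) in case series: {dupes}")
    return EpidemicSeries(dates=dates, counts=tuple(p[1] for p in pairs))


def write_case_series(series: EpidemicSeries, path: str | Path) -> None:
    pd.DataFrame(
        {"date": [d.isoformat() for d in series.dates], "new_cases": list(series.counts)}
    ).to_csv(path, index=False)
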