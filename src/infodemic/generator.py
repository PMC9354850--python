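"""Synthetic corpus generator with planted, recoverable structure.

Every analysis stage in this package is validated against corpora whose
ground truth is known by construction.  The generator emulates the posting
record of a panel of government health accounts during an epidemic wave:

* a log-normal-shaped daily curve of newly confirmed cases (Poisson counts);
* total daily post volumes tied to that curve at a *planted Pearson
  correlation* ``rho`` via a Gaussian copula whose latent correlation is
  calibrated to the target count-scale correlation;
* a 24-hour posting profile (morning peak at 08:00 by default);
* six content types mixed per week, with the science/debunking share
  falling and the assistance-story share rising over the wave;
* titles assembled from the true type's keyword lexicon plus Zipf-distributed
  filler words, whitespace-joined so the default tokenizer recovers them
  exactly (``chinese_mode`` emits unsegmented strings for pluggable
  segmenters);
* verbatim duplicate titles planted across account pairs at configured
  expected counts (Poisson), with all *other* titles kept globally unique by
  rejection so the planted duplication matrix is the exact ground truth;
* log-normal read counts display-censored at the platform cap, and likes
  binomially thinned from the *uncensored* reads.

Identical ``(config, seed)`` always yields a byte-identical corpus.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import stats

from . import reference
from .content_types import DEFAULT_KEYWORDS, N_TYPES
from .corpus import Corpus, EpidemicSeries, TweetRecord
from .independence import normalize_title


class GeneratorError(ValueError):
    """Raised for invalid generator configuration."""


# --------------------------------------------------------------------------
# defaults


def default_hour_profile() -> np.ndarray:
    """Posting-hour probabilities: near-silent overnight, peak at 08:00,
    secondary afternoon/evening activity."""
    p = np.array(
        [0.001] * 7  # 00..06
        + [0.02, 0.18, 0.08, 0.07, 0.05,  # 07..11
           0.04, 0.03, 0.04, 0.05, 0.07,  # 12..16
           0.06, 0.04, 0.04, 0.04, 0.04,  # 17..21
           0.05, 0.05]                     # 22..23
    )
    return p / p.sum()


def default_type_mixture(n_weeks: int) -> np.ndarray:
    """Week-by-week content-type probabilities (rows sum to 1).

    Encodes the qualitative trends of the emulated corpus: science and
    disinformation posts start dominant and decline; assistance stories rise;
    impact/reopening posts appear from mid-wave; overview and negative-impact
    shares stay roughly flat.
    """
    if n_weeks < 1:
        raise GeneratorError("need at least one week")
    rows = []
    for w in range(n_weeks):
        f = w / max(1, n_weeks - 1)
        science = 0.40 - 0.27 * f
        aid = 0.10 + 0.30 * f
        impact = 0.01 + 0.09 * max(0.0, (f - 0.45) / 0.55)
        negative = 0.012
        overview = 0.19
        control = 1.0 - (overview + science + aid + impact + negative)
        rows.append([overview, control, science, aid, impact, negative])
    mixture = np.array(rows)
    if np.any(mixture <= 0):
        raise GeneratorError("degenerate default mixture")
    return mixture


def default_account_weights(n_accounts: int) -> np.ndarray:
    """Share of daily volume per account; for a 10-account panel, the
    published per-account proportions of the motivating corpus."""
    if n_accounts == len(reference.ACCOUNT_TWEET_COUNTS):
        w = np.array(list(reference.ACCOUNT_TWEET_COUNTS.values()), dtype=float)
        return w / w.sum()
    return np.full(n_accounts, 1.0 / n_accounts)


def default_dup_rates(n_accounts: int, rate: float = 3.0) -> np.ndarray:
    m = np.full((n_accounts, n_accounts), float(rate))
    np.fill_diagonal(m, 0.0)
    return m


@dataclasses.dataclass(frozen=True)
class CurveShape:
    """Log-normal-shaped epidemic curve: expected daily cases
    H * exp(-(ln((t+1)/(peak_day+1)))^2 / (2 * width^2)) for day index t."""

    peak_day: int = 25
    width: float = 0.6
    peak_height: float = 4000.0


@dataclasses.dataclass
class GeneratorConfig:
    """All planted parameters of a synthetic corpus.

    Defaults emulate the motivating panel: 10 accounts posting
    2020-01-17..2020-03-31 (~88 posts/day in total), daily volume correlated
    with the case curve at rho = 0.721, an 08:00 posting peak, week-varying
    six-type content mixture, a constant cross-account duplicate-title rate,
    log-normal reads censored at 100,000, and like counts thinned from reads.
    """

    n_accounts: int = 10
    start: dt.date = dt.date(2020, 1, 17)
    end: dt.date = dt.date(2020, 3, 31)
    curve: CurveShape = dataclasses.field(default_factory=CurveShape)
    rho: float = reference.DAILY_POST_CASE_CORRELATION
    mean_daily_posts: float = 88.0
    account_ids: tuple[str, ...] | None = None
    account_weights: np.ndarray | None = None
    hour_profile: np.ndarray = dataclasses.field(default_factory=default_hour_profile)
    type_mixture: np.ndarray | None = None  # (n_weeks, 6); default trend mixture
    type_lexicons: Mapping[int, Sequence[str]] = dataclasses.field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_KEYWORDS.items()}
    )
    zipf_exponent: float = 1.1
    vocab_size: int = 300
    dup_rates: np.ndarray | None = None  # (n_accounts, n_accounts), zero diagonal
    keywords_per_title: tuple[int, int] = (1, 3)
    filler_per_title: tuple[int, int] = (2, 5)
    p_original: float = 0.9
    read_log_mean: float = 8.2
    read_log_sigma: float = 1.3
    read_cap: int = 100_000
    like_beta_a: float = 1.0
    like_beta_b: float = 199.0
    watch_rate: float = 0.02
    comment_rate: float = 0.1  # of likes
    collection_lag_days: int = 7
    chinese_mode: bool = False
    seed: int = 0

    # -- derived -----------------------------------------------------------

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1

    @property
    def n_weeks(self) -> int:
        return -(-self.n_days // 7)

    @property
    def dates(self) -> list[dt.date]:
        return [self.start + dt.timedelta(days=i) for i in range(self.n_days)]

    def resolved_account_ids(self) -> tuple[str, ...]:
        if self.account_ids is not None:
            return tuple(self.account_ids)
        return tuple(f"account_{i + 1:02d}" for i in range(self.n_accounts))

    def resolved_account_weights(self) -> np.ndarray:
        if self.account_weights is not None:
            return np.asarray(self.account_weights, dtype=float)
        return default_account_weights(self.n_accounts)

    def resolved_type_mixture(self) -> np.ndarray:
        if self.type_mixture is not None:
            return np.asarray(self.type_mixture, dtype=float)
        return default_type_mixture(self.n_weeks)

    def resolved_dup_rates(self) -> np.ndarray:
        if self.dup_rates is not None:
            return np.asarray(self.dup_rates, dtype=float)
        return default_dup_rates(self.n_accounts)

    def validate(self) -> None:
        if self.n_days < 2:
            raise GeneratorError("date range must span at least 2 days")
        if not -1.0 <= self.rho <= 1.0:
            raise GeneratorError(f"rho must be in [-1, 1], got {self.rho}")
        ids = self.resolved_account_ids()
        if len(ids) != self.n_accounts or len(set(ids)) != self.n_accounts:
            raise GeneratorError("account_ids must be n_accounts unique labels")
        w = self.resolved_account_weights()
        if w.shape != (self.n_accounts,) or abs(w.sum() - 1.0) > 1e-9 or np.any(w < 0):
            raise GeneratorError("account_weights must be a probability vector")
        h = np.asarray(self.hour_profile, dtype=float)
        if h.shape != (24,) or abs(h.sum() - 1.0) > 1e-9 or np.any(h < 0):
            raise GeneratorError("hour_profile must be a 24-long probability vector")
        mix = self.resolved_type_mixture()
        if mix.ndim != 2 or mix.shape[1] != N_TYPES or np.any(mix < 0):
            raise GeneratorError("type_mixture must be (n_weeks, 6) and nonnegative")
        if np.any(np.abs(mix.sum(axis=1) - 1.0) > 1e-9):
            raise GeneratorError("each type_mixture row must sum to 1")
        dup = self.resolved_dup_rates()
        if dup.shape != (self.n_accounts, self.n_accounts):
            raise GeneratorError("dup_rates shape must be (n_accounts, n_accounts)")
        if not np.allclose(dup, dup.T) or np.any(np.diagonal(dup) != 0) or np.any(dup < 0):
            raise GeneratorError("dup_rates must be symmetric, nonnegative, zero-diagonal")
        if set(self.type_lexicons) != set(range(1, N_TYPES + 1)):
            raise GeneratorError("type_lexicons must cover type codes 1..6")
        if not 0 < self.keywords_per_title[0] <= self.keywords_per_title[1]:
            raise GeneratorError("keywords_per_title must be a positive (lo, hi) pair")
        if not 0 <= self.filler_per_title[0] <= self.filler_per_title[1]:
            raise GeneratorError("filler_per_title must be a (lo, hi) pair")

    def lexicons_disjoint(self) -> bool:
        seen: set[str] = set()
        for words in self.type_lexicons.values():
            ws = set(words)
            if seen & ws:
                return False
            seen |= ws
        return True

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["start"] = self.start.isoformat()
        d["end"] = self.end.isoformat()
        d["hour_profile"] = [float(x) for x in self.hour_profile]
        for key in ("account_weights", "type_mixture", "dup_rates"):
            if d[key] is not None:
                d[key] = np.asarray(d[key], dtype=float).tolist()
        d["type_lexicons"] = {int(k): list(v) for k, v in self.type_lexicons.items()}
        d["account_ids"] = list(self.account_ids) if self.account_ids else None
        d["keywords_per_title"] = list(self.keywords_per_title)
        d["filler_per_title"] = list(self.filler_per_title)
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "GeneratorConfig":
        d = dict(data)
        d["start"] = dt.date.fromisoformat(d["start"])
        d["end"] = dt.date.fromisoformat(d["end"])
        if isinstance(d.get("curve"), Mapping):
            d["curve"] = CurveShape(**d["curve"])
        if d.get("hour_profile") is not None:
            d["hour_profile"] = np.asarray(d["hour_profile"], dtype=float)
        for key in ("account_weights", "type_mixture", "dup_rates"):
            if d.get(key) is not None:
                d[key] = np.asarray(d[key], dtype=float)
        if d.get("account_ids") is not None:
            d["account_ids"] = tuple(d["account_ids"])
        if d.get("type_lexicons") is not None:
            d["type_lexicons"] = {int(k): tuple(v) for k, v in d["type_lexicons"].items()}
        for key in ("keywords_per_title", "filler_per_title"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    """Planted parameters realized in an emitted corpus."""

    true_types: tuple[int, ...]
    account_ids: tuple[str, ...]
    planted_pair_counts: np.ndarray  # realized duplicate pairs per account pair
    dup_rates: np.ndarray            # expected duplicate pairs per account pair
    rho: float
    hour_profile: np.ndarray
    daily_posts: np.ndarray
    daily_cases: np.ndarray

    def to_dict(self) -> dict:
        return {
            "true_types": list(self.true_types),
            "account_ids": list(self.account_ids),
            "planted_pair_counts": self.planted_pair_counts.astype(int).tolist(),
            "dup_rates": self.dup_rates.tolist(),
            "rho": float(self.rho),
            "hour_profile": self.hour_profile.tolist(),
            "daily_posts": self.daily_posts.astype(int).tolist(),
            "daily_cases": self.daily_cases.astype(int).tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)


# --------------------------------------------------------------------------
# epidemic curve


def generate_epidemic_curve(config: GeneratorConfig, seed=None) -> EpidemicSeries:
    """Poisson daily case counts around a log-normal-shaped mean curve.

    Deterministic given the seed (default: ``config.seed``); the expected
    curve rises to ``curve.peak_day`` and decays, emulating a contained
    first epidemic wave.
    """
    if config.n_days < 2:
        raise GeneratorError("date range must span at least 2 days")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    t = np.arange(config.n_days, dtype=float)
    shape = config.curve
    if shape.peak_height <= 0:
        mean = np.zeros(config.n_days)
    else:
        log_ratio = np.log((t + 1.0) / (shape.peak_day + 1.0))
        mean = shape.peak_height * np.exp(-(log_ratio**2) / (2.0 * shape.width**2))
    counts = rng.poisson(mean)
    return EpidemicSeries(dates=tuple(config.dates), counts=tuple(int(c) for c in counts))


# --------------------------------------------------------------------------
# daily volumes via Gaussian copula


def _normal_scores(x: np.ndarray) -> np.ndarray:
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf(ranks / (len(x) + 1.0))


def _volume_marginal(u: np.ndarray, cases: np.ndarray, mean_daily: float) -> np.ndarray:
    """Post-count marginal: affine map of the empirical case quantile at u,
    with a 30% volume floor so posting never dies out entirely."""
    b0 = 0.3 * mean_daily
    mean_c = cases.mean()
    b1 = 0.7 * mean_daily / mean_c if mean_c > 0 else 0.0
    q = np.quantile(cases, u, method="linear")
    return np.maximum(0, np.rint(b0 + b1 * q)).astype(np.int64)


_CALIBRATION_CACHE: dict[tuple, float] = {}
_CALIBRATION_SEED = 987_654_321
_CALIBRATION_REPS = 400


def _mean_count_pearson(r_lat: float, z: np.ndarray, eps: np.ndarray,
                        cases: np.ndarray, mean_daily: float) -> float:
    w = r_lat * z[None, :] + np.sqrt(max(0.0, 1.0 - r_lat**2)) * eps
    posts = _volume_marginal(stats.norm.cdf(w), cases, mean_daily).astype(float)
    pc = posts - posts.mean(axis=1, keepdims=True)
    cc = cases - cases.mean()
    denom = np.sqrt((pc**2).sum(axis=1) * (cc**2).sum())
    with np.errstate(invalid="ignore"):
        r = (pc @ cc) / denom
    return float(np.nanmean(r))


def _calibrate_latent_rho(cases: np.ndarray, rho: float, mean_daily: float) -> float:
    """Latent normal correlation whose induced count-scale Pearson matches
    ``rho`` in expectation.  Deterministic (fixed internal seed) and cached
    per (curve, rho, volume)."""
    key = (cases.tobytes(), round(float(rho), 9), round(float(mean_daily), 9))
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]
    rng = np.random.default_rng(_CALIBRATION_SEED)
    z = _normal_scores(cases)
    eps = rng.standard_normal((_CALIBRATION_REPS, len(cases)))

    def f(r_lat: float) -> float:
        return _mean_count_pearson(r_lat, z, eps, cases, mean_daily)

    # The attainable count-scale correlation is bounded by the
    # Frechet-Hoeffding limits of the (identically shaped) count margins;
    # skewed margins push the lower limit well above -1.  Clamp to the
    # nearest attainable value before bisecting.
    if rho >= f(1.0):
        r_lat = 1.0
    elif rho <= f(-1.0):
        r_lat = -1.0
    else:
        lo, hi = -1.0, 1.0
        for _ in range(24):
            mid = 0.5 * (lo + hi)
            if f(mid) < rho:
                lo = mid
            else:
                hi = mid
        r_lat = 0.5 * (lo + hi)
    _CALIBRATION_CACHE[key] = r_lat
    return r_lat


def generate_daily_volumes(
    cases: np.ndarray | EpidemicSeries,
    rho: float,
    mean_daily: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Total daily post counts whose Pearson correlation with ``cases`` is
    planted at ``rho`` (Gaussian copula, calibrated on the count scale).

    At ``|rho| = 1`` the copula degenerates to an exact (anti)monotone affine
    map of the case counts; at ``rho = 0`` volumes are independent of the
    curve.  A flat case curve falls back to Poisson volumes.
    """
    if isinstance(cases, EpidemicSeries):
        cases = np.asarray(cases.counts, dtype=float)
    cases = np.asarray(cases, dtype=float)
    n = len(cases)
    if np.ptp(cases) == 0:
        return rng.poisson(mean_daily, size=n).astype(np.int64)
    z = _normal_scores(cases)
    if rho >= 1.0:
        u = stats.norm.cdf(z)
    elif rho <= -1.0:
        u = stats.norm.cdf(-z)
    elif rho == 0.0:
        u = stats.norm.cdf(rng.standard_normal(n))
    else:
        r_lat = _calibrate_latent_rho(cases, rho, mean_daily)
        w = r_lat * z + np.sqrt(1.0 - r_lat**2) * rng.standard_normal(n)
        u = stats.norm.cdf(w)
    return _volume_marginal(u, cases, mean_daily)


# --------------------------------------------------------------------------
# corpus assembly


def _filler_vocabulary(config: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    words = np.array([f"w{i:04d}" for i in range(config.vocab_size)])
    ranks = np.arange(1, config.vocab_size + 1, dtype=float)
    p = ranks ** (-config.zipf_exponent)
    return words, p / p.sum()


def _draw_title(
    rng: np.random.Generator,
    type_code: int,
    lexicon_words: Mapping[int, np.ndarray],
    filler_words: np.ndarray,
    filler_p: np.ndarray,
    config: GeneratorConfig,
    used: set[str],
) -> str:
    kw_lo, kw_hi = config.keywords_per_title
    fl_lo, fl_hi = config.filler_per_title
    n_kw = int(rng.integers(kw_lo, kw_hi + 1))
    n_fl = int(rng.integers(fl_lo, fl_hi + 1))
    tokens = list(rng.choice(lexicon_words[type_code], size=n_kw, replace=True))
    tokens += list(filler_words[rng.choice(len(filler_words), size=n_fl, p=filler_p)])
    order = rng.permutation(len(tokens))
    tokens = [tokens[i] for i in order]
    sep = "" if config.chinese_mode else " "
    title = sep.join(tokens)
    # keep non-planted titles globally unique so duplication ground truth is exact
    while normalize_title(title) in used:
        extra = filler_words[int(rng.choice(len(filler_words), p=filler_p))]
        title = title + sep + extra if sep else title + extra
    used.add(normalize_title(title))
    return title


def generate_corpus(
    config: GeneratorConfig,
    curve: EpidemicSeries | None = None,
    seed=None,
) -> tuple[Corpus, GroundTruth]:
    """Emit a corpus plus its ground truth.  See the module docstring for the
    planted structure.  ``seed`` overrides ``config.seed``."""
    config.validate()
    if not config.lexicons_disjoint():
        raise GeneratorError(
            "type lexicons overlap; classifier ground truth would be ambiguous"
        )
    entropy = config.seed if seed is None else seed
    root = entropy if isinstance(entropy, np.random.SeedSequence) else np.random.SeedSequence(entropy)
    s_curve, s_vol, s_posts, s_dups, s_eng = root.spawn(5)
    if curve is None:
        curve = generate_epidemic_curve(config, seed=s_curve)
    if len(curve) != config.n_days:
        raise GeneratorError(
            f"curve has {len(curve)} days but config spans {config.n_days}"
        )
    cases = np.asarray(curve.counts, dtype=float)

    posts_per_day = generate_daily_volumes(
        cases, config.rho, config.mean_daily_posts, np.random.default_rng(s_vol)
    )

    rng = np.random.default_rng(s_posts)
    accounts = config.resolved_account_ids()
    weights = config.resolved_account_weights()
    mixture = config.resolved_type_mixture()
    hour_p = np.asarray(config.hour_profile, dtype=float)
    lexicon_words = {k: np.asarray(list(v)) for k, v in config.type_lexicons.items()}
    filler_words, filler_p = _filler_vocabulary(config)
    used_titles: set[str] = set()

    drafts: list[dict] = []  # engagement attached later, vectorized
    for day_idx, date in enumerate(config.dates):
        alloc = rng.multinomial(posts_per_day[day_idx], weights)
        week = min(day_idx // 7, mixture.shape[0] - 1)
        for acct_idx, n_posts in enumerate(alloc):
            if n_posts == 0:
                continue
            types = rng.choice(N_TYPES, size=n_posts, p=mixture[week]) + 1
            hours = rng.choice(24, size=n_posts, p=hour_p)
            minutes = rng.integers(0, 60, size=n_posts)
            originals = rng.random(n_posts) < config.p_original
            for t, h, m, orig in zip(types, hours, minutes, originals):
                title = _draw_title(
                    rng, int(t), lexicon_words, filler_words, filler_p, config, used_titles
                )
                drafts.append(
                    {
                        "account_id": accounts[acct_idx],
                        "title": title,
                        "is_original": bool(orig),
                        "posted_at": dt.datetime(
                            date.year, date.month, date.day, int(h), int(m)
                        ),
                        "content_type": int(t),
                    }
                )

    # planted cross-account duplicates
    dup_rng = np.random.default_rng(s_dups)
    dup_rates = config.resolved_dup_rates()
    planted = np.zeros((config.n_accounts, config.n_accounts), dtype=int)
    n_days = config.n_days
    for i in range(config.n_accounts):
        for j in range(i + 1, config.n_accounts):
            k = int(dup_rng.poisson(dup_rates[i, j]))
            planted[i, j] = planted[j, i] = k
            for _ in range(k):
                week = int(dup_rng.integers(0, mixture.shape[0]))
                t = int(dup_rng.choice(N_TYPES, p=mixture[min(week, mixture.shape[0] - 1)])) + 1
                title = _draw_title(
                    dup_rng, t, lexicon_words, filler_words, filler_p, config, used_titles
                )
                for acct_idx, original in ((i, True), (j, False)):
                    day = int(dup_rng.integers(0, n_days))
                    date = config.dates[day]
                    h = int(dup_rng.choice(24, p=hour_p))
                    m = int(dup_rng.integers(0, 60))
                    drafts.append(
                        {
                            "account_id": accounts[acct_idx],
                            "title": title,
                            "is_original": original,
                            "posted_at": dt.datetime(
                                date.year, date.month, date.day, h, m
                            ),
                            "content_type": t,
                        }
                    )

    drafts.sort(key=lambda r: (r["posted_at"], r["account_id"], r["title"]))

    # engagement, vectorized over the whole corpus
    eng = np.random.default_rng(s_eng)
    n = len(drafts)
    true_reads = np.rint(
        eng.lognormal(config.read_log_mean, config.read_log_sigma, size=n)
    ).astype(np.int64)
    censored = true_reads >= config.read_cap
    shown_reads = np.where(censored, config.read_cap, true_reads)
    p_like = eng.beta(config.like_beta_a, config.like_beta_b, size=n)
    likes = eng.binomial(true_reads, p_like)
    watches = eng.binomial(true_reads, config.watch_rate)
    comments = eng.binomial(likes, config.comment_rate)

    records = tuple(
        TweetRecord(
            account_id=d["account_id"],
            title=d["title"],
            is_original=d["is_original"],
            read_count=int(shown_reads[idx]),
            read_censored=bool(censored[idx]),
            posted_at=d["posted_at"],
            watch_count=int(watches[idx]),
            like_count=int(likes[idx]),
            comment_count=int(comments[idx]),
            article_url=f"https://posts.example/{d['account_id']}/{idx}",
            cover_url=f"https://covers.example/{d['account_id']}/{idx}",
            content_type=d["content_type"],
        )
        for idx, d in enumerate(drafts)
    )
    corpus = Corpus(
        records=records,
        collection_date=config.end + dt.timedelta(days=config.collection_lag_days),
    )
    truth = GroundTruth(
        true_types=tuple(d["content_type"] for d in drafts),
        account_ids=accounts,
        planted_pair_counts=planted,
        dup_rates=dup_rates,
        rho=config.rho,
        hour_profile=hour_p,
        daily_posts=posts_per_day.copy(),
        daily_cases=np.asarray(curve.counts, dtype=np.int64),
    )
    return corpus, truth
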