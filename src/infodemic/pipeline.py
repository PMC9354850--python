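"""End-to-end report pipeline: corpus + case series in, table suite out.

Runs every analysis stage in sequence and writes a tidy report bundle —
per-account counts, type taxonomy tables, engagement summary, temporal
series, correlation, the communication-index ranking and high-index screen,
the duplication/overlap network, and the co-word network — plus a manifest
recording the config hash, seed, package version and record counts at every
stage.  Conservation is enforced: per-account and per-type counts must both
total the corpus size.  Output is deterministic for fixed inputs.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .content_types import (
    TypeLexicon,
    classify_corpus,
    default_lexicon,
    type_counts,
    type_distribution,
    weekly_type_proportions,
)
from .corpus import Corpus, CorpusError, read_case_series, read_corpus
from .coword import build_coword, degree_centrality
from .independence import duplication_matrix, strength_sums, to_ucinet_dl, valued_density
from .stci import engagement_summary, high_stci_breakdown, high_stci_filter, score_corpus
from .temporal import daily_counts, hourly_profile, pearson, period_summary


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""


@dataclasses.dataclass
class PipelineConfig:
    """Paths, thresholds and toggles for one pipeline run."""

    corpus_path: str
    cases_path: str
    out_dir: str
    lexicon_path: str | None = None
    stoplist_path: str | None = None
    collection_date: dt.date | None = None
    stci_threshold: float = 800.0
    min_freq: int = 60
    top_k: int = 100
    read_cap: int = 100_000
    reads_over: int = 10_000
    period_days: int = 7
    matcher: str = "exact"
    sim_threshold: float = 0.8
    density_mode: str = "mean"
    coword_marginals: str = "occurrence"
    fallback_type: int | None = 3
    seed: int = 0

    def validate(self) -> None:
        for name in ("stci_threshold", "min_freq", "top_k", "read_cap", "reads_over", "period_days"):
            if getattr(self, name) <= 0:
                raise PipelineError(f"{name} must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.collection_date is not None:
            d["collection_date"] = self.collection_date.isoformat()
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if data.get("collection_date"):
            data["collection_date"] = dt.date.fromisoformat(str(data["collection_date"]))
        return cls(**data)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write the report bundle; returns the manifest.

    Any stage error is re-raised as :class:`PipelineError` naming the stage.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }

    def stage(name: str):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    corpus = stage("load_corpus")(
        lambda: read_corpus(
            config.corpus_path,
            collection_date=config.collection_date,
            read_cap=config.read_cap,
        )
    )
    cases = stage("load_cases")(lambda: read_case_series(config.cases_path))
    manifest["stages"]["load_corpus"] = len(corpus)
    manifest["stages"]["load_cases"] = len(cases)

    lexicon = (
        TypeLexicon.from_yaml(config.lexicon_path)
        if config.lexicon_path
        else default_lexicon(fallback=config.fallback_type)
    )
    if any(r.content_type is None for r in corpus.records):
        corpus = stage("classify")(lambda: classify_corpus(corpus, lexicon))
    manifest["stages"]["classify"] = len(corpus)

    # account and taxonomy bookkeeping (with conservation checks)
    frame = corpus.to_frame()
    account_counts = frame.groupby("account_id").size().sort_values(ascending=False, kind="stable")
    per_type = stage("type_counts")(lambda: type_counts(corpus))
    if int(account_counts.sum()) != len(corpus) or int(per_type.sum()) != len(corpus):
        raise PipelineError("stage 'bookkeeping' failed: counts do not total the corpus size")
    account_counts.rename("n_tweets").to_csv(out / "account_counts.csv")
    per_type.rename("n_tweets").rename_axis("content_type").to_csv(out / "type_counts.csv")
    manifest["stages"]["account_counts_total"] = int(account_counts.sum())
    manifest["stages"]["type_counts_total"] = int(per_type.sum())

    stage("type_distribution")(lambda: type_distribution(corpus)).round(6).to_csv(
        out / "type_distribution_pct.csv"
    )
    stage("weekly_proportions")(lambda: weekly_type_proportions(corpus)).round(6).to_csv(
        out / "weekly_type_proportions.csv"
    )

    engagement = stage("engagement")(
        lambda: engagement_summary(corpus, reads_over=config.reads_over)
    )
    engagement.round(6).to_csv(out / "engagement_summary.csv")

    daily = stage("daily_counts")(lambda: daily_counts(corpus))
    daily.rename_axis("date").to_csv(out / "daily_counts.csv")
    hourly = stage("hourly_profile")(lambda: hourly_profile(corpus))
    pd.Series(hourly, name="posts").rename_axis("hour").to_csv(out / "hourly_profile.csv")
    stage("period_summary")(lambda: period_summary(daily, config.period_days)).to_csv(
        out / "period_summary.csv", index=False
    )

    corr = stage("correlation")(lambda: pearson(daily, cases))
    with open(out / "correlation.json", "w", encoding="utf-8") as fh:
        json.dump({"r": corr.r, "p_value": corr.p_value, "n": corr.n}, fh, indent=1)
    manifest["stages"]["correlation_n_days"] = corr.n

    scored = stage("stci")(lambda: score_corpus(corpus))
    scored.round({"score": 6}).to_csv(out / "stci_scores.csv", index=False)
    high = stage("high_stci")(lambda: high_stci_filter(scored, config.stci_threshold))
    high.round({"score": 6}).to_csv(out / "high_stci.csv", index=False)
    breakdown = high_stci_breakdown(high)
    breakdown["by_account"].rename("n_tweets").to_csv(out / "high_stci_by_account.csv")
    breakdown["by_type"].rename("n_tweets").to_csv(out / "high_stci_by_type.csv")
    manifest["stages"]["stci_scored"] = len(scored)
    manifest["stages"]["high_stci"] = len(high)

    dup = stage("duplication")(
        lambda: duplication_matrix(corpus, matcher=config.matcher, sim_threshold=config.sim_threshold)
    )
    dup.to_frame().to_csv(out / "duplication_matrix.csv")
    (out / "duplication_matrix.dl").write_text(to_ucinet_dl(dup), encoding="utf-8")
    strength_sums(dup).to_csv(out / "overlap_strength.csv")
    density = valued_density(dup, mode=config.density_mode)
    manifest["stages"]["duplication_density"] = density

    stoplist: tuple[str, ...] = ()
    if config.stoplist_path:
        stoplist = tuple(
            w.strip() for w in Path(config.stoplist_path).read_text(encoding="utf-8").splitlines()
            if w.strip()
        )
    freqs, coword = stage("coword")(
        lambda: build_coword(
            corpus,
            stoplist=stoplist,
            min_freq=config.min_freq,
            top_k=config.top_k,
            marginals=config.coword_marginals,
        )
    )
    freqs.rename_axis("term").to_csv(out / "term_frequencies.csv")
    coword.counts.to_frame().to_csv(out / "cooccurrence_counts.csv")
    coword.ochiai.to_frame().round(6).to_csv(out / "ochiai_matrix.csv")
    (out / "ochiai_matrix.dl").write_text(to_ucinet_dl(coword.ochiai), encoding="utf-8")
    degree_centrality(coword.ochiai, mode="binary").round(6).rename_axis("term").to_csv(
        out / "degree_centrality.csv"
    )
    manifest["stages"]["coword_terms"] = len(coword.terms)
    manifest["stages"]["coword_density"] = valued_density(coword.ochiai, mode=config.density_mode)

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
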