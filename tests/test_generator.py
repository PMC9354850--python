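import dataclasses
import datetime as dt

import numpy as np
import pytest
from scipy import stats

from infodemic import (
    CurveShape,
    GeneratorConfig,
    generate_corpus,
    generate_daily_volumes,
    generate_epidemic_curve,
    normalize_title,
    write_corpus,
)
from infodemic.generator import (
    GeneratorError,
    default_dup_rates,
    default_hour_profile,
    default_type_mixture,
)


class TestEpidemicCurve:
    def test_zero_peak_height_gives_all_zero_series(self, small_config):
        config = dataclasses.replace(small_config, curve=CurveShape(peak_height=0.0))
        curve = generate_epidemic_curve(config, seed=5)
        assert all(c == 0 for c in curve.counts)

    def test_deterministic_given_seed(self, small_config):
        a = generate_epidemic_curve(small_config, seed=42)
        b = generate_epidemic_curve(small_config, seed=42)
        assert a == b

    def test_degenerate_date_range_rejected(self):
        config = GeneratorConfig(start=dt.date(2020, 1, 1), end=dt.date(2020, 1, 1))
        with pytest.raises(GeneratorError):
            generate_epidemic_curve(config)

    def test_peak_day_recovered_by_monte_carlo(self):
        """The empirical argmax of the mean curve sits at the configured peak
        (within one day) across 500 replicates."""
        config = GeneratorConfig(
            start=dt.date(2020, 1, 1),
            end=dt.date(2020, 3, 15),  # 75 days
            curve=CurveShape(peak_day=20, width=0.6, peak_height=500.0),
        )
        total = np.zeros(config.n_days)
        for seed in range(500):
            total += generate_epidemic_curve(config, seed=seed).counts
        assert abs(int(np.argmax(total)) - 20) <= 1


class TestDailyVolumes:
    def _cases(self, n=365, seed=0):
        config = GeneratorConfig(
            start=dt.date(2020, 1, 21),
            end=dt.date(2020, 1, 21) + dt.timedelta(days=n - 1),
            curve=CurveShape(peak_day=20, width=0.6, peak_height=4000.0),
        )
        return np.asarray(generate_epidemic_curve(config, seed=seed).counts, dtype=float)

    def test_degenerate_copula_rho_one(self):
        """rho=1 collapses to a monotone affine map of the cases, so the
        sample correlation is 1 up to integer rounding."""
        cases = self._cases()
        posts = generate_daily_volumes(cases, 1.0, 88.0, np.random.default_rng(0))
        assert stats.pearsonr(posts, cases).statistic > 0.999

    def test_rho_minus_one_is_antimonotone(self):
        """rho=-1 couples posts anti-monotonically to cases; the rank
        correlation hits the Frechet lower bound even though the Pearson
        floor of two identically skewed count margins sits above -1."""
        cases = self._cases()
        posts = generate_daily_volumes(cases, -1.0, 88.0, np.random.default_rng(0))
        assert stats.spearmanr(posts, cases).statistic < -0.95
        assert stats.pearsonr(posts, cases).statistic < 0

    def test_flat_curve_falls_back_to_poisson(self):
        posts = generate_daily_volumes(np.zeros(100), 0.7, 50.0, np.random.default_rng(1))
        assert posts.min() >= 0 and abs(posts.mean() - 50.0) < 5.0

    def test_planted_rho_recovered(self):
        """Mean sample r over 200 volume draws lands within 0.03 of the
        planted value (the published-scale rho, n=365 days)."""
        cases = self._cases()
        rs = [
            stats.pearsonr(
                generate_daily_volumes(cases, 0.7, 88.0, np.random.default_rng(seed)), cases
            ).statistic
            for seed in range(200)
        ]
        assert abs(np.mean(rs) - 0.7) < 0.03


class TestCorpusGeneration:
    def test_reproducible_byte_identical(self, small_config, tmp_path):
        corpus_a, truth_a = generate_corpus(small_config)
        corpus_b, truth_b = generate_corpus(small_config)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        write_corpus(corpus_a, pa)
        write_corpus(corpus_b, pb)
        assert pa.read_bytes() == pb.read_bytes()
        assert truth_a.true_types == truth_b.true_types
        assert np.array_equal(truth_a.planted_pair_counts, truth_b.planted_pair_counts)

    def test_zero_dup_rates_means_no_shared_titles(self, small_config):
        config = dataclasses.replace(small_config, dup_rates=np.zeros((4, 4)))
        corpus, _ = generate_corpus(config)
        seen: dict[str, str] = {}
        for r in corpus.records:
            canon = normalize_title(r.title)
            assert seen.setdefault(canon, r.account_id) == r.account_id
        # stronger: rejection keeps every canonical title globally unique
        assert len(seen) == len(corpus)

    def test_planted_duplicates_exist_verbatim_in_both_accounts(self, small_config):
        corpus, truth = generate_corpus(small_config)
        titles_by_account = {
            a: {normalize_title(r.title) for r in corpus.records if r.account_id == a}
            for a in truth.account_ids
        }
        shared = np.zeros_like(truth.planted_pair_counts)
        for i, a in enumerate(truth.account_ids):
            for j, b in enumerate(truth.account_ids):
                if i < j:
                    n = len(titles_by_account[a] & titles_by_account[b])
                    shared[i, j] = shared[j, i] = n
        assert np.array_equal(shared, truth.planted_pair_counts)

    def test_titles_use_only_lexicon_and_filler_vocabulary(self, small_config):
        corpus, truth = generate_corpus(small_config)
        lexicon_words = {w for ws in small_config.type_lexicons.values() for w in ws}
        for r in corpus.records[:200]:
            for tok in r.title.split():
                assert tok in lexicon_words or tok.startswith("w")

    def test_hour_profile_recovered_in_total_variation(self):
        """Empirical hour histogram of a ~10,000-post corpus is within total
        variation 0.02 of the planted profile."""
        config = GeneratorConfig(mean_daily_posts=140.0, dup_rates=np.zeros((10, 10)), seed=2)
        corpus, truth = generate_corpus(config)
        assert len(corpus) >= 10_000
        hist = np.zeros(24)
        for r in corpus.records:
            hist[r.posted_hour] += 1
        tv = 0.5 * np.abs(hist / hist.sum() - truth.hour_profile).sum()
        assert tv <= 0.02

    def test_censoring_rate_monotone_in_read_location(self, small_config):
        rates = []
        for mu in (7.0, 9.0, 11.0):
            config = dataclasses.replace(small_config, read_log_mean=mu)
            corpus, _ = generate_corpus(config)
            rates.append(np.mean([r.read_censored for r in corpus.records]))
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] > rates[0]

    def test_censored_records_sit_at_the_cap(self, small_config):
        config = dataclasses.replace(small_config, read_log_mean=11.0)
        corpus, _ = generate_corpus(config)
        censored = [r for r in corpus.records if r.read_censored]
        assert censored and all(r.read_count == config.read_cap for r in censored)

    def test_overlapping_lexicons_rejected(self, small_config):
        lex = {k: tuple(v) for k, v in small_config.type_lexicons.items()}
        lex[2] = lex[2] + (next(iter(lex[1])),)
        config = dataclasses.replace(small_config, type_lexicons=lex)
        with pytest.raises(GeneratorError, match="overlap"):
            generate_corpus(config)

    def test_config_yaml_round_trip(self, small_config, tmp_path):
        path = tmp_path / "config.yaml"
        small_config.to_yaml(path)
        loaded = GeneratorConfig.from_yaml(path)
        corpus_a, _ = generate_corpus(small_config)
        corpus_b, _ = generate_corpus(loaded)
        assert corpus_a.records == corpus_b.records


class TestDefaults:
    def test_probability_vectors_are_normalized(self):
        assert abs(default_hour_profile().sum() - 1.0) < 1e-9
        mixture = default_type_mixture(11)
        assert np.allclose(mixture.sum(axis=1), 1.0, atol=1e-9)
        assert mixture.shape == (11, 6)

    def test_default_hour_peak_is_eight(self):
        assert int(np.argmax(default_hour_profile())) == 8

    def test_science_share_falls_and_aid_share_rises(self):
        mixture = default_type_mixture(10)
        assert mixture[0, 2] > mixture[-1, 2]  # science and disinformation
        assert mixture[0, 3] < mixture[-1, 3]  # assistance stories

    def test_dup_rates_matrix_is_valid(self):
        m = default_dup_rates(5, rate=4.0)
        assert np.allclose(m, m.T) and np.all(np.diagonal(m) == 0)

    def test_invalid_rho_rejected(self, small_config):
        config = dataclasses.replace(small_config, rho=1.5)
        with pytest.raises(GeneratorError, match="rho"):
            config.validate()
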