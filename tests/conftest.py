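import datetime as dt

import pytest

from infodemic import Corpus, CurveShape, GeneratorConfig, TweetRecord
from infodemic.generator import default_dup_rates


def make_record(
    account="acct_a",
    title="virus mask update",
    reads=500,
    likes=5,
    censored=False,
    when=dt.datetime(2020, 2, 1, 8, 30),
    content_type=None,
    **kwargs,
):
    return TweetRecord(
        account_id=account,
        title=title,
        is_original=True,
        read_count=reads,
        read_censored=censored,
        posted_at=when,
        like_count=likes,
        content_type=content_type,
        **kwargs,
    )


@pytest.fixture
def tiny_corpus():
    """Hand-built 8-record corpus over 3 accounts and 4 days."""
    d = dt.datetime
    records = (
        make_record("a", "cases confirmed w001", 12000, 10, when=d(2020, 2, 1, 8, 0), content_type=1),
        make_record("a", "virus mask w002", 8000, 20, when=d(2020, 2, 1, 9, 30), content_type=3),
        make_record("a", "volunteer heroes w003", 100000, 30, censored=True, when=d(2020, 2, 2, 8, 15), content_type=4),
        make_record("b", "policy lockdown notice", 4000, 4, when=d(2020, 2, 2, 16, 0), content_type=2),
        make_record("b", "reopening school w004", 15000, 40, when=d(2020, 2, 3, 8, 45), content_type=5),
        make_record("b", "cases confirmed w001", 600, 1, when=d(2020, 2, 3, 23, 5), content_type=1),
        make_record("c", "corruption penalty w005", 900, 2, when=d(2020, 2, 4, 12, 10), content_type=6),
        make_record("c", "virus rumor myth w006", 30000, 60, when=d(2020, 2, 4, 8, 50), content_type=3),
    )
    return Corpus(records=records, collection_date=dt.date(2020, 2, 10))


@pytest.fixture(scope="session")
def small_config():
    """Reduced generator setup: 4 accounts over 4 weeks, ~20 posts/day."""
    return GeneratorConfig(
        n_accounts=4,
        start=dt.date(2020, 2, 1),
        end=dt.date(2020, 2, 28),
        curve=CurveShape(peak_day=10, width=0.5, peak_height=800.0),
        mean_daily_posts=20.0,
        dup_rates=default_dup_rates(4, rate=2.0),
        seed=11,
    )
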