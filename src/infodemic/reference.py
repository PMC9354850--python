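"""Published summary statistics of the motivating corpus.

The pipeline was designed around the COVID-19 posting record of ten Chinese
provincial health-commission official accounts (articles published
2020-01-17 through 2020-03-31, engagement figures collected afterwards).
The raw corpus is not publicly deposited, but its headline bookkeeping
numbers are, and they serve two roles here: as published-table inputs whose
internal consistency the pipeline enforces on any corpus, and as realistic
defaults for the synthetic-corpus generator.
"""

from __future__ import annotations

#: Post count per official account over the collection window.
ACCOUNT_TWEET_COUNTS: dict[str, int] = {
    "Healthy Beijing": 242,
    "Healthy Guangdong": 1174,
    "Healthy Hubei": 904,
    "Healthy Hunan": 70,
    "Healthy Jiangsu": 475,
    "Healthy Shanghai": 360,
    "Healthy Sichuan official": 771,
    "Healthy Tianjin": 1586,
    "Healthy Zhejiang": 543,
    "Chongqing Health and hygiene": 487,
}

#: Post count per content type (codes 1..6) over the same corpus.
CONTENT_TYPE_COUNTS: dict[int, int] = {
    1: 1210,  # epidemic overview release
    2: 1362,  # epidemic prevention and control measures
    3: 1739,  # science and disinformation
    4: 1952,  # epidemic line assistance stories
    5: 275,   # epidemic impact
    6: 74,    # negative impact
}

#: Published total size of the corpus (both tables above must sum to it).
CORPUS_TOTAL: int = 6612

#: Published Pearson correlation between daily article volume and daily
#: newly confirmed cases over the same period.
DAILY_POST_CASE_CORRELATION: float = 0.721

#: Published modal posting hour (24h clock).
PEAK_POSTING_HOUR: int = 8

#: Screening threshold for "high communication power" posts, and the number
#: of posts that exceeded it in the motivating corpus.
HIGH_STCI_THRESHOLD: float = 800.0
HIGH_STCI_COUNT: int = 67
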