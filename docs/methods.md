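# Methods

This note records the models, conventions and numerical choices behind
`infodemic`, in the package's own words. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The communication index

The STCI (single-tweet communication index) is a member of the WeChat
Communication Index (WCI) family of log-blend engagement scores. We evaluate

    STCI = 10 * [ 0.6 * (0.2 ln(R/d + 1) + 0.8 ln(R + 1))
                + 0.4 * (0.2 ln(10Z/d + 1) + 0.8 ln(10Z + 1)) ]^2

with R cumulative reads, Z cumulative likes, d the inclusive day count from
posting date to collection date. Four rendering choices are deliberate and
isolated in `stci.compute_stci`:

1. the per-day terms are R/d and 10·Z/d (day-averaged rates, as in the WCI
   family), not R·d;
2. the read/like weights are 0.6/0.4 (so they sum to 1);
3. the inner blend is squared and then scaled by 10;
4. likes are multiplied by 10 before the log, putting them on a magnitude
   comparable to reads.

This is the only reading under which realistic strong posts
(R ~ 10^4–10^5, Z ~ 10^2–10^4) score in the 900–1,100 band that published
high-index tables occupy; alternative literal readings either explode with d
or collapse the scale. The index is zero iff R = Z = 0, strictly increasing
in R and Z, and non-increasing in d (all property-tested on a grid).

**Day convention.** d counts both endpoints: a post collected on its posting
day has d = 1, which keeps the rate terms finite without a special case.
Posting dates after the collection date are an error.

**Censoring.** The platform displays at most `read_cap` (default 100,000)
reads. Censored posts are parsed as `(cap, censored=True)` and scored at the
cap — a lower bound on the true score — with the flag propagated through the
ranking. No imputation is attempted because the censoring mechanism gives no
usable tail information at the single-post level.

## Duplication / independence network

Titles are canonicalized (casefold, punctuation stripped, whitespace
collapsed). The pairwise matrix entry (i, j) counts matched title pairs
between accounts i and j with each post matched at most once per counterpart
account: for exact matching this is Σ_t min(count_i(t), count_j(t)) over
canonical titles t; for similarity matching, a greedy one-to-one assignment
in descending token-Jaccard order above a threshold. We report per-account
row sums as *overlap strength*: the literature sometimes labels this quantity
"independence strength", but it measures overlap, so independence is its
inverse ranking — the naming here keeps the computation identical while
fixing the semantics.

**Density.** For a valued network we default to the mean off-diagonal tie
value over all n(n−1) ordered cells (the UCINET valued convention); a binary
mode (share of nonzero ties) and a raw-sum mode are available, because
published "density" figures for count-valued networks are only interpretable
as a mean or a sum, and sources rarely say which convention their tool used.

## Co-word network

Term frequencies are occurrence counts (a token twice in one title counts
2); co-occurrence X_AB is presence-based (a title contributes at most 1 per
pair). High-frequency selection keeps terms with count strictly above
`min_freq` (default 60), truncated to `top_k` (default 100) with ties broken
lexicographically for determinism. The Ochiai transform is
y = X_AB / √(X_A·X_B). With presence-based X_AB, the bound
X_AB ≤ min(df_A, df_B) ≤ min(X_A, X_B) ≤ √(X_A·X_B) holds whether the
marginals X_A are occurrence counts (the default, matching how frequency
tables are usually published) or document frequencies, so y ∈ [0, 1] under
both conventions; the choice is a flag (`marginals=`). Degree centrality is
binary (share of nonzero neighbors, computed on the dichotomized graph via
networkx) or valued (row sums of y).

**Tokenization.** The tokenizer is a pluggable callable (title → raw
tokens); the default splits canonicalized text on whitespace. Part-of-speech
selection (e.g. keeping only nouns/verbs) belongs inside a custom tokenizer;
no Chinese segmenter is bundled, but any (e.g. a jieba wrapper) satisfies the
contract. The stoplist is applied after canonicalization.

## Temporal analyses

Daily series are zero-filled over a contiguous date range. Pearson r is
computed on the intersection of dates (scipy.stats.pearsonr; the two-sided p
equals the t-transform formula, which a test verifies independently).
Constant series and n < 3 are errors rather than NaNs. Period box-plot
summaries use linear-interpolation quartiles (numpy's default "linear"
method, the inclusive convention) — box-plot quartile conventions differ
across tools, so this is stated rather than assumed.

## Content typing

Manual coding is replaced by a keyword-lexicon classifier: the type with the
most keyword hits (counted with multiplicity) wins, ties break by a
configurable priority order, and zero hits fall back to `unclassified` or a
configured default type. This is transparent and auditable but only *exact*
on corpora whose lexicons are disjoint by construction — on real corpora it
is a rough proxy for human coding, and accuracy claims in the test suite
apply to synthetic data only. Weekly mixtures use 7-day bins anchored at the
corpus start; the final bin may be partial (a 75-day window yields 11 bins,
the last 5 days long).

## Synthetic corpus generator

Defaults emulate the motivating panel: 10 accounts, 2020-01-17..2020-03-31
(75 days), ~88 posts/day in total split by the panel's published per-account
proportions, planted post/case correlation 0.721, an 08:00 posting peak with
a near-silent 00:00–07:00 trough, a week-varying type mixture (science share
0.40 → 0.13, assistance share 0.10 → 0.40, impact growing from mid-wave),
a constant duplicate rate of 3 expected shared titles per account pair,
log-normal reads (location 8.2, scale 1.3, giving a mean around 10^4 and a
few-percent censoring rate at the 100,000 cap), and likes
Binomial(true reads, p) with p ~ Beta(1, 199) (mean 0.5%), yielding average
like counts in the tens, the scale seen in published engagement tables.
Likes, watches and comments thin the *uncensored* reads, since platform like
counts are not capped.

**Correlation planting.** Daily volumes couple to the case curve through a
Gaussian copula: the latent normal for day t is
w_t = ρ_lat·z_t + √(1−ρ_lat²)·ε_t with z the normal scores of the case
counts, and the volume marginal is an affine map of the empirical case
quantile function (floor 30% of mean volume, so posting never dies out).
Because count margins are skewed and rounding intervenes, the latent ρ_lat
does not equal the count-scale Pearson target, so ρ_lat is calibrated by a
deterministic Monte-Carlo bisection (fixed internal seed, 400 replicates,
cached per curve/target). Consequences worth knowing:

* at ρ = 1 the coupling degenerates to a monotone affine map of the cases —
  the sample correlation is 1 up to integer rounding (~1−10⁻⁴);
* the attainable correlation range is the Fréchet–Hoeffding interval of the
  count margins; for identically shaped skewed margins the lower limit sits
  well above −1, and targets outside the attainable range are clamped to the
  nearest endpoint;
* a flat (zero-variance) case curve falls back to Poisson volumes,
  independent of the curve.

**Duplicates and title uniqueness.** Planted duplicates are drawn
Poisson(rate) per account pair and copied verbatim into both accounts at
independent times; *all other* titles are kept globally unique by appending
filler tokens until the canonical form is unused. This makes the planted
pair-count matrix the exact ground truth for the exact matcher, at the cost
of ruling out accidental within-account repeats — acceptable because the
matcher, not natural title entropy, is what is under test.

**What the generator does not emulate.** Real title semantics (titles are
keyword + Zipf-filler bags, so co-word structure beyond planted hubs is
uninformative); engagement dependence on content quality, account size or
time of day; censoring-by-account heterogeneity; reposting cascades; and any
platform algorithmic feedback. Tests that pass on synthetic corpora
establish the correctness of the *computations*, not the field validity of
the measures.

## Problem sizes and determinism

The test suite and the acceptance script size their simulations to the
precision each check needs: 200 volume draws over a 365-day curve for
correlation recovery (Monte-Carlo s.e. of the mean ≈ 0.002 against a ±0.03
band), 50 corpora of ~800 posts for duplicate-rate recovery (s.e. ≈ 0.4
against a 15% band at rate 8), ~1,200 posts for classifier recovery and
~10,700 for the hour-profile check. All randomness flows from
numpy `SeedSequence` roots, so identical (config, seed) pairs produce
byte-identical corpora and report bundles; analysis stages contain no
randomness at all.

## Known limitations

* The lexicon classifier is not a substitute for trained human coding on
  real corpora.
* The similarity matcher is quadratic per account pair; use exact matching
  for corpora beyond a few thousand posts per account.
* Censored reads make high-STCI rankings lower bounds; two capped posts with
  different true reads can tie.
* Published density figures from GUI network tools can follow either the
  mean or the sum convention; compare like with like before quoting.
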