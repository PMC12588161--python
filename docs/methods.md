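# Methods

This note documents the statistical procedures `lingtrait` implements, the
assumptions behind them, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
choices that matter for reproducibility.

## The measurement model

Generalized trust is treated as a scalar trait per person. Two measurements
of it coexist in the package:

* a **survey score** — the mean of a short Likert scale after reverse-coding
  flagged items (x → min + max − x), with reliability summarized by
  Cronbach's α = k/(k−1) · (1 − Σ var(itemᵢ) / var(Σ items)), computed on
  complete cases with sample (ddof = 1) variances;
* a **language score** — an affine function of the person's language
  features, learned by ridge regression against the survey score.

Observed correlations with either score understate the latent association
because both measures are noisy; the disattenuated correlation
r / √(rel_x · rel_y) corrects for that, clipped to [−1, 1] (sampling error
can push the corrected value out of range; the clip is warned about, never
silent).

## Language features

Messages are tokenized with a rule-based social-media tokenizer: lowercase;
emoticons (`:)`, `<3`), hashtags, punctuation runs (`!!!`) and internal
apostrophes (`can't`) are preserved as single tokens; URLs and @-mentions
collapse to `<url>` / `<user>` sentinels. These choices follow from the
observation that trait signal lives in exactly such tokens (exclamation
runs, emoticons) and would be destroyed by a conventional word tokenizer.

Three feature families are built per user:

1. **Relative n-gram frequencies** (n = 1..3). N-grams never cross message
   boundaries (messages are independent utterances). The denominator for a
   feature of order n is the user's *pre-filter* total count of order-n
   grams, so rows remain comparable however the vocabulary is pruned; a
   row's retained mass is ≤ 1, with equality when nothing was filtered.
2. **Binary n-grams** — 1 if the user ever used the feature, else 0.
3. **Topic usage** — p(topic|user) = Σ_w p(topic|w) · relfreq(w|user), the
   natural probabilistic composition of a word→topic weight lexicon with
   the user's unigram distribution. Topic lexicons are consumed, never
   trained, here.

Two filters define the vocabulary, both fitted on a reference corpus and
then frozen (the `FeaturePipeline`), so that time-binned or
community-aggregated matrices share columns with the training matrix:

* **Collocation filter**: a phrase w₁..wₙ is kept iff its pointwise mutual
  information log₂[p(phrase)/∏p(wᵢ)] ≥ θ·(n−1), with θ = 3 per gap by
  default. PMI is the standard collocation statistic; the per-gap scaling
  makes the threshold comparable across bigrams and trigrams. θ is
  configurable because no canonical value exists; 3 bits per gap demands
  roughly an 8-fold joint-over-chance excess, which keeps grammatical
  accidents out while admitting genuine phrases.
* **Coverage filter**: a feature must be used by ≥ 10% of users
  (inclusive boundary — "at least"). This suppresses rare, idiosyncratic
  language that would otherwise dominate a mass-univariate screen.

Users enter feature extraction only with ≥ 1,000 tokens total (inclusive),
the conventional floor for having an adequate language sample per person.

## Differential language analysis

For each feature: z-score the feature and the outcome, fit OLS of the
outcome on the feature plus covariates, and report the coefficient on the
feature (a standardized β; with no covariates it equals the Pearson
correlation exactly — an identity the tests assert at 1e−10). The 95% CI
and two-tailed p come from the coefficient's t distribution. Zero-variance
features are skipped and logged; collinear designs raise.

All p-values of one analysis run receive a single joint Benjamini–Hochberg
step-up correction (flags plus monotone q-values). The implementation is
statsmodels'; an implementation-from-definition oracle in the test suite
checks it exhaustively on random p-vectors.

Dictionary categories (LIWC-style) are scored as the summed relative
frequency of unigrams matched by the category's patterns, where a trailing
`*` is a prefix wildcard; category screening then reuses the same
machinery. Word-cloud tables scale display size to 100·|β|/max|β| and bin
corpus frequency by terciles (gray/blue/red). The rank-difference
moderation display ranks significant features by |β| within each group and
sign (ties averaged), compares each feature's rank to the other group's
(or the mean of the other groups'), colors non-positive differences gray
and positive ones green with shade linear in the difference, capped at the
95th percentile; features absent from a comparison group's list take
sentinel rank m+1.

## The trait model

Per feature family, on training rows only:

1. keep features whose univariate Pearson p is below 0.05 (uncorrected — a
   deliberately permissive screen whose only job is to drop pure noise
   columns; configurable);
2. standardize and project onto principal components, with
   k = min(⌊0.10·N_train⌋, rank) — capping model dimensionality at 10% of
   the observations controls variance at the expense of bias;
3. standardize the components (keeps the ridge penalty isotropic across
   families; no whitening).

The concatenated components feed ridge regression; the penalty is chosen
by k-fold (default 10) cross-validated MSE over a log grid 10⁰..10⁵ with a
seeded shuffle, then the model is refit on all training rows. PCA is
computed by full SVD (deterministic up to sign; any sign flip is absorbed
by the ridge weights, so predictions are reproducible — the fit is
byte-identical from (inputs, seed)). Models serialize to a single sorted
JSON document (schema-versioned).

At predict time the stored standardization, loadings and weights make the
scorer an affine map; missing feature columns are imputed as 0 (absence of
a word is a true zero), but prediction refuses to run if fewer than half
of a family's features resolve. Test–retest reliability re-extracts
features per half-year bin with the frozen vocabulary, scores users with
≥ min posts in every bin, and reports all pairwise Pearson correlations.

## Community level

User features are averaged (unweighted — mirroring the mean of a survey
sample) over users with ≥ 30 posts, and communities with < 100 qualifying
users are dropped; both thresholds inclusive. Because the scorer is
affine, aggregate-then-score equals score-then-average exactly — asserted
in the tests, and the reason community scoring needs no per-user pass.

Community correlates regress each outcome (dependent) on the community
trust score (independent), reporting the unadjusted Pearson r and the
covariate-adjusted standardized β, with one joint BH-FDR over outcomes.
Region enters as 3 dummies from 4 labels (reference-cell coding; the
adjusted β is invariant to which region is the reference). Outcome cells
backed by too few survey respondents are blanked before analysis
(per-outcome thresholds); outcomes observed in < 10 communities are
skipped. Log-transforming skewed outcomes is the caller's choice, exposed
as a per-column flag in the outcome metadata.

## Affect contrast

Each message's raw affect is the mean lexicon weight over matched tokens;
unmatched messages are excluded by default (a configurable flag — the
alternative scores them 0, which dilutes the baseline toward whatever the
lexicon's zero means). Raw scores are z-normalized across all scored
messages, which makes subset contrasts invariant to the lexicon's scale
and offset. Subset means carry normal-approximation 95% CIs
(mean ± 1.96·sd/√n); subsets smaller than 2 get flagged NaN CIs.
`split_category` partitions a dictionary category into a removal set
(e.g. *people*/*they* — "othering" references to unspecific others) and
its complement, each re-usable in the category screen; expanding wildcard
patterns against the corpus vocabulary first guarantees the two parts
partition the category's matches.

## The synthetic generator

The generator is the package's evidence base, so its defaults are fixed
study conditions, not tuning knobs:

| parameter | default | meaning |
|---|---|---|
| n_users | 2,000 | population size |
| posts_per_user | Poisson(50) | posts per user |
| tokens_per_post | Poisson(30) | tokens per post (~1,500 words/user) |
| vocab_size | 600 | shifted-Zipf baseline vocabulary (p ∝ 1/(rank+10)) |
| loaded lexicons | +0.5 / −0.5 | affiliative vs. othering word lists (11 entries each, incl. one two-word phrase) |
| lexicon_base_rate | 0.08 | per-lexicon mixture weight at trust = 0 |
| survey | 3 items, α = 0.73 | one item reverse-coded, 1–5 Likert |
| age / gender r | 0.06 / 0.08 | weak demographic correlations with trust |
| communities | 100, between-sd 0.3 | users partitioned evenly |
| outcome effects | ±0.4, 0 | standardized effects of community mean trust |

Token emission: per token, each loaded lexicon is selected with probability
2·base_rate·σ(loading·trust) (a logistic mixture — equal to base_rate at
trust 0 and always a valid probability, unlike additive per-token rates),
the baseline Zipf distribution takes the remainder. Latent trust is
marginally standard normal, decomposed as community effect (sd 0.3) plus
within-community deviation. Survey items are parallel measures
item = λ·trust + σ·ε with λ² the inter-item correlation obtained by
inverting Spearman–Brown for the target α, inflated by a Sheppard-type
correction (adding the 1/12 rounding variance) so that the *discretized*
1–5 responses, not the continuous latents, realize the target. Outcomes
are effect·z(community mean trust) + √(1−effect²)·noise, so the planted
standardized effect equals the configured value. Timestamps are uniform
over four half-year windows (Jul 2009–Jun 2011) to exercise test–retest.
All draws flow through one explicit `numpy.random.Generator`; every
artifact is byte-reproducible from (config, seed).

What the generator does **not** emulate: grammar or topical coherence
(baseline tokens are exchangeable), message-length/verbosity effects
correlated with traits, demographic structure beyond the two configured
correlations, non-random community assignment (no selective migration),
and measurement artifacts of real platforms (duplicates, bots, language
mixing). Passing recovery tests therefore demonstrate that the *pipeline*
is correct and calibrated — not that real social-media language carries
this much trust signal; on real data the attainable accuracy is an
empirical question.

## Validation experiments (lingtrait.validation)

* **Null FDR calibration** — 20 replicates of a 500-user population with
  all loadings 0; the mean fraction of FDR-flagged features must not
  exceed α plus twice the Monte-Carlo SE. (BH controls the FDR, so under a
  global null the flagged fraction is far below α.)
* **Trust recovery** — the default 2,000-user population, 80/20 split;
  the model is trained on the *survey* score (reliability ≈ 0.73, as a
  real study would be) and evaluated against the latent trust score on
  held-out users. The acceptance floor is r ≥ 0.6; the generator's
  defaults put the realized value around 0.9.
* **Community effect recovery** — 500 communities × 4 users, planted
  standardized effect 0.4, 20 seeds; the mean adjusted β must land within
  ±0.08 of the plant, and a parallel zero-effect outcome stays unflagged.
* **Othering dissociation** — signal planted only on *people*/*they*;
  splitting the social category must yield a significantly negative β for
  the othering part and a non-significant, near-zero β for the remainder.

Problem sizes (500–2,000 users, 20 replicates) were chosen so each
experiment is a single-CPU, minutes-scale computation while keeping
Monte-Carlo error well inside the asserted margins.

## Numerical and edge-case policies

* Inclusive thresholds everywhere a floor is stated (1,000 words, 10%
  coverage, 30 posts, 100 users, respondent minima).
* Complete-case survey scoring by default; incomplete respondents are
  dropped with a warning.
* Empirical age terciles break ties toward the lower bin; the life-stage
  mode uses ≤18 / 19–23 / ≥24.
* Ranking ties get average ranks.
* Zero-variance features: skipped in screening (logged), error in a single
  requested association.
* Degenerate corpora: an all-users-filtered corpus raises
  `EmptyCorpusError`; a user with a zero order-total gets a zero row and a
  warning; an empty significant-feature set yields an empty word-cloud
  table with a notice.
* Determinism: no global random state anywhere; every stochastic routine
  takes a seed or Generator, and fitted models, feature matrices and
  simulated corpora are byte-identical across reruns.

## Known limitations

* Phrase statistics beyond PMI (e.g. likelihood-ratio tests) are not
  offered; PMI with a per-gap threshold is the single collocation
  criterion.
* The univariate screen ignores feature correlation; PCA afterwards
  handles redundancy but the screen itself can admit many copies of one
  signal.
* Ridge penalty selection assumes exchangeable rows (plain k-fold CV); no
  grouping structure (e.g. by community) is respected during CV.
* The affect scorer is a lexicon mean — no negation handling, no context.
* Community inference is ecological: a county-level β says nothing about
  individual-level causation.
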