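"""Seeded synthetic corpora, surveys, communities and outcomes.

Every other module is recovery-testable against this generator: users carry
a latent standard-normal trust score; token emission mixes a Zipf-like
baseline vocabulary with trust-loaded word lists whose mixture weight is a
logistic function of (loading × trust); survey items are parallel measures
whose loading is chosen in closed form to hit a target Cronbach's alpha;
users nest in communities whose mean trust drives outcome variables with a
configured standardized effect.

All randomness flows through one explicitly passed ``numpy.random.Generator``
— no global state — so every artifact is byte-reproducible from
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .community import OutcomeTable
from .corpus import Message, MessageCorpus

__all__ = [
    "LoadedLexicon",
    "OutcomeSpec",
    "SimConfig",
    "SyntheticGroundTruth",
    "SimData",
    "simulate_ground_truth",
    "simulate_corpus",
    "simulate_survey",
    "simulate_communities",
    "simulate_all",
    "region_dummies",
    "TRUST_TOKENS",
    "DISTRUST_TOKENS",
]

# Trust-loaded demonstration vocabularies: affiliative / future-oriented
# words for high trust, angry / othering words for distrust.  Multiword
# entries are emitted as adjacent tokens, so they surface as collocations.
TRUST_TOKENS = (
    "love", "friends", "we", "thanks", "excited", "tomorrow",
    "great", "amazing", "party", "family", "looking forward",
)
DISTRUST_TOKENS = (
    "hate", "stupid", "people", "they", "never", "hell",
    "kill", "alone", "pain", "wrong", "tired of",
)

# four half-year windows (UTC) used for message timestamps
TIME_BINS = tuple(
    (datetime(y1, m1, 1), datetime(y2, m2, 1))
    for (y1, m1), (y2, m2) in [
        ((2009, 7), (2010, 1)),
        ((2010, 1), (2010, 7)),
        ((2010, 7), (2011, 1)),
        ((2011, 1), (2011, 7)),
    ]
)


@dataclass(frozen=True)
class LoadedLexicon:
    tokens: tuple[str, ...]
    loading: float

    def __post_init__(self) -> None:
        if abs(self.loading) > 1:
            raise ValueError("|loading| must be at most 1")


@dataclass(frozen=True)
class OutcomeSpec:
    name: str
    effect: float  # standardized effect of community mean trust
    min_respondents: int = 0


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; the defaults are the package's study conditions."""

    n_users: int = 2000
    posts_per_user: float = 50.0
    tokens_per_post: float = 30.0
    vocab_size: int = 600
    loaded_lexicons: tuple[LoadedLexicon, ...] = (
        LoadedLexicon(TRUST_TOKENS, 0.5),
        LoadedLexicon(DISTRUST_TOKENS, -0.5),
    )
    lexicon_base_rate: float = 0.08  # mixture weight per lexicon at trust=0
    survey_items: int = 3
    survey_alpha: float = 0.73
    response_min: int = 1
    response_max: int = 5
    age_trust_r: float = 0.06
    gender_trust_r: float = 0.08
    female_fraction: float = 0.57
    n_communities: int = 100
    between_community_sd: float = 0.3
    outcomes: tuple[OutcomeSpec, ...] = (
        OutcomeSpec("life_satisfaction", 0.4, min_respondents=200),
        OutcomeSpec("poor_health", -0.4, min_respondents=200),
        OutcomeSpec("unrelated", 0.0, min_respondents=0),
    )
    respondents_mean: float = 400.0

    def __post_init__(self) -> None:
        if self.n_users < 1 or self.n_communities < 1:
            raise ValueError("counts must be at least 1")
        if self.vocab_size < 2:
            raise ValueError("vocabulary needs at least 2 tokens")
        if not 0 < self.survey_alpha <= 1:
            raise ValueError("target reliability must be in (0, 1]")
        total = 2 * self.lexicon_base_rate * len(self.loaded_lexicons)
        if total >= 1:
            raise ValueError("lexicon mixture weights can exceed 1; lower "
                             "lexicon_base_rate")


@dataclass
class SyntheticGroundTruth:
    """Latent quantities the generator planted, for recovery tests."""

    users: pd.DataFrame  # user_id, trust, age, gender, community_id
    community_trust: pd.Series  # realized mean latent trust per community
    config: SimConfig
    seed: int | None = None
    community_effects: pd.Series | None = None  # generative community draws

    @property
    def trust(self) -> pd.Series:
        return self.users.set_index("user_id")["trust"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_ground_truth(
    config: SimConfig, rng: np.random.Generator
) -> SyntheticGroundTruth:
    """Draw communities, latent trust, and demographics.

    Users are partitioned evenly over communities; trust decomposes into a
    community mean (sd = ``between_community_sd``) plus a within-community
    deviation scaled so the marginal trust distribution is standard normal.
    Age and gender get small positive correlations with trust, mirroring
    weak demographic associations.
    """
    n = config.n_users
    m = config.n_communities
    tau = config.between_community_sd
    if tau > 1:
        raise ValueError("between-community sd cannot exceed 1")
    comm_ids = np.array([f"c{i % m:04d}" for i in range(n)])
    comm_means = rng.normal(0.0, tau, size=m)
    within = rng.normal(0.0, np.sqrt(max(1 - tau**2, 0.0)), size=n)
    trust = comm_means[np.arange(n) % m] + within

    eps = rng.normal(size=n)
    r_age = config.age_trust_r
    age_latent = r_age * trust + np.sqrt(1 - r_age**2) * eps
    age = np.clip(np.round(23 + 9 * age_latent), 13, 80).astype(int)

    eps = rng.normal(size=n)
    r_g = config.gender_trust_r
    gender_latent = r_g * trust + np.sqrt(1 - r_g**2) * eps
    from scipy.stats import norm

    cut = norm.ppf(1 - config.female_fraction)
    gender = (gender_latent > cut).astype(int)  # 1 = female

    users = pd.DataFrame(
        {
            "user_id": [f"u{i:05d}" for i in range(n)],
            "trust": trust,
            "age": age,
            "gender": gender,
            "community_id": comm_ids,
        }
    )
    community_trust = (
        users.groupby("community_id")["trust"].mean().rename("mean_trust")
    )
    effects = pd.Series(
        comm_means,
        index=[f"c{i:04d}" for i in range(m)],
        name="community_effect",
    ).sort_index()
    return SyntheticGroundTruth(
        users=users,
        community_trust=community_trust,
        config=config,
        community_effects=effects,
    )


def _base_distribution(vocab_size: int) -> tuple[list[str], np.ndarray]:
    """Shifted-Zipf baseline vocabulary (flat enough that most words clear
    a 10% user-coverage filter at the default corpus size)."""
    words = [f"w{i:04d}" for i in range(vocab_size)]
    ranks = np.arange(1, vocab_size + 1)
    probs = 1.0 / (ranks + 10)
    return words, probs / probs.sum()


def simulate_corpus(
    config: SimConfig,
    rng: np.random.Generator,
    ground_truth: SyntheticGroundTruth | None = None,
) -> tuple[MessageCorpus, SyntheticGroundTruth]:
    """Generate timestamped messages whose vocabulary leaks latent trust.

    Per token the emitting source is a mixture: each loaded lexicon has
    weight 2·base_rate·sigmoid(loading·trust) (equal to ``base_rate`` at
    trust 0), the baseline Zipf vocabulary takes the remainder.  Message
    timestamps are uniform over four half-year bins.
    """
    if ground_truth is None:
        ground_truth = simulate_ground_truth(config, rng)
    base_words, base_probs = _base_distribution(config.vocab_size)
    lexicons = config.loaded_lexicons
    bin_starts = np.array(
        [b[0].timestamp() for b in TIME_BINS]
    )
    bin_lengths = np.array(
        [(b[1] - b[0]).total_seconds() for b in TIME_BINS]
    )

    messages: list[Message] = []
    msg_counter = 0
    for row in ground_truth.users.itertuples(index=False):
        t = row.trust
        weights = np.array(
            [2 * config.lexicon_base_rate * _sigmoid(lex.loading * t)
             for lex in lexicons]
        )
        w_base = 1.0 - weights.sum()
        n_posts = max(int(rng.poisson(config.posts_per_user)), 1)
        post_lengths = rng.poisson(config.tokens_per_post, size=n_posts)
        post_lengths = np.maximum(post_lengths, 1)
        total = int(post_lengths.sum())
        # source per token: 0 = baseline, 1..L = lexicons
        source = rng.choice(
            len(lexicons) + 1,
            size=total,
            p=np.concatenate([[w_base], weights]),
        )
        tokens = np.empty(total, dtype=object)
        base_mask = source == 0
        n_base = int(base_mask.sum())
        if n_base:
            tokens[base_mask] = rng.choice(
                base_words, size=n_base, p=base_probs
            )
        for li, lex in enumerate(lexicons, start=1):
            mask = source == li
            n_lex = int(mask.sum())
            if n_lex:
                tokens[mask] = rng.choice(np.array(lex.tokens), size=n_lex)
        offsets = rng.integers(0, 4, size=n_posts)
        secs = bin_starts[offsets] + rng.random(n_posts) * bin_lengths[offsets]
        pos = 0
        for k in range(n_posts):
            length = int(post_lengths[k])
            text = " ".join(tokens[pos : pos + length])
            pos += length
            messages.append(
                Message(
                    user_id=row.user_id,
                    message_id=f"m{msg_counter:08d}",
                    created_at=datetime.utcfromtimestamp(round(secs[k])),
                    text=text,
                )
            )
            msg_counter += 1
    return MessageCorpus(messages), ground_truth


def simulate_survey(
    ground_truth: SyntheticGroundTruth,
    config: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Likert item responses whose k-item alpha targets ``survey_alpha``.

    Items are parallel: item = λ·trust + σ·noise with λ² the inter-item
    correlation implied by the target alpha (Spearman–Brown inverted),
    inflated by a Sheppard-type correction for the variance the Likert
    rounding adds.  The last item is emitted reverse-coded.
    """
    k = config.survey_items
    target = config.survey_alpha
    if k < 1:
        raise ValueError("need at least one survey item")
    rho = target / (k - target * (k - 1))
    spread = 0.9  # sd of the continuous response on the Likert scale
    rho_cont = rho * (spread**2 + 1 / 12) / spread**2
    if rho_cont >= 1.0:
        if target >= 0.999:
            lam, sigma = 1.0, 0.0
        else:
            raise ValueError(
                f"target alpha {target} unattainable for {k} items on a "
                "discretized scale"
            )
    else:
        lam = np.sqrt(rho_cont)
        sigma = np.sqrt(1 - rho_cont)

    trust = ground_truth.trust
    n = len(trust)
    mid = (config.response_min + config.response_max) / 2
    data = {}
    for j in range(k):
        latent = lam * trust.to_numpy() + sigma * rng.normal(size=n)
        resp = np.clip(
            np.round(mid + spread * latent),
            config.response_min,
            config.response_max,
        )
        if j == k - 1:  # reverse-coded item, e.g. "suspect hidden motives"
            resp = config.response_min + config.response_max - resp
        data[f"item_{j + 1}"] = resp
    return pd.DataFrame(data, index=trust.index)


def simulate_communities(
    ground_truth: SyntheticGroundTruth,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[pd.Series, OutcomeTable]:
    """User→community map plus outcomes driven by community mean trust.

    Each outcome equals effect·z(community mean trust) plus Gaussian noise
    with variance 1−effect², so the generative standardized effect is the
    configured value.  Community respondent counts are Poisson, and region
    labels are uniform over the four Census regions for covariate tests.
    """
    users = ground_truth.users
    community_map = users.set_index("user_id")["community_id"]
    means = ground_truth.community_trust
    z = (means - means.mean()) / means.std(ddof=0)
    values = {}
    n_resp = {}
    min_resp = {}
    for spec in config.outcomes:
        noise = rng.normal(size=len(z))
        values[spec.name] = (
            spec.effect * z.to_numpy()
            + np.sqrt(max(1 - spec.effect**2, 0.0)) * noise
        )
        n_resp[spec.name] = rng.poisson(config.respondents_mean, size=len(z))
        min_resp[spec.name] = spec.min_respondents
    regions = rng.choice(
        ["northeast", "south", "west", "midwest"], size=len(z)
    )
    covariates = pd.get_dummies(
        pd.Series(regions, index=z.index, name="region")
    ).astype(float)
    outcomes = OutcomeTable(
        values=pd.DataFrame(values, index=z.index),
        n_respondents=pd.DataFrame(n_resp, index=z.index),
        min_respondents=min_resp,
        covariates=covariates,
    )
    return community_map, outcomes


def region_dummies(
    covariates: pd.DataFrame, reference: str = "midwest"
) -> list[str]:
    """Region indicator columns with one reference level dropped."""
    cols = [c for c in covariates.columns if c != reference]
    if len(cols) == len(covariates.columns):
        raise KeyError(f"reference region {reference!r} not found")
    return cols


def synthetic_topic_lexicon(
    vocab_size: int = 600, n_topics: int = 20
) -> "TopicLexicon":
    """A synthetic word→topic lexicon matching the generator's vocabulary.

    Baseline words are assigned round-robin to ``n_topics`` topics with
    weight 1; the trust- and distrust-loaded demonstration words get their
    own two topics, so topic usage carries trait signal the way coherent
    word clusters would.
    """
    from .features import TopicLexicon

    rows = []
    for i in range(vocab_size):
        rows.append({"term": f"w{i:04d}", "topic_id": i % n_topics,
                     "weight": 1.0})
    for tok in TRUST_TOKENS:
        for part in tok.split():
            rows.append({"term": part, "topic_id": n_topics, "weight": 1.0})
    for tok in DISTRUST_TOKENS:
        for part in tok.split():
            rows.append({"term": part, "topic_id": n_topics + 1,
                         "weight": 1.0})
    df = pd.DataFrame(rows).drop_duplicates(subset=["term", "topic_id"])
    return TopicLexicon(table=df)


@dataclass
class SimData:
    corpus: MessageCorpus
    survey: pd.DataFrame
    ground_truth: SyntheticGroundTruth
    community_map: pd.Series
    outcomes: OutcomeTable


def simulate_all(config: SimConfig, seed: int) -> SimData:
    """One seeded draw of every artifact the pipeline consumes."""
    rng = np.random.default_rng(seed)
    ground_truth = simulate_ground_truth(config, rng)
    ground_truth.seed = seed
    corpus, _ = simulate_corpus(config, rng, ground_truth)
    survey = simulate_survey(ground_truth, config, rng)
    community_map, outcomes = simulate_communities(ground_truth, config, rng)
    return SimData(
        corpus=corpus,
        survey=survey,
        ground_truth=ground_truth,
        community_map=community_map,
        outcomes=outcomes,
    )


def boundary_fixture() -> dict:
    """Deterministic fixtures sitting exactly on every inclusion boundary.

    Returns a dict with:

    * ``word_corpus`` — users with exactly 999 and 1000 tokens;
    * ``coverage_corpus`` — features used by exactly 9 and 10 of 100 users;
    * ``posts_per_user`` / ``community_map`` / ``user_features`` — users at
      29/30 posts and communities with 99/100 qualifying users.
    """
    word_messages = [
        Message("u999", "wm0", datetime(2010, 1, 1), " ".join(["alpha"] * 999)),
        Message("u1000", "wm1", datetime(2010, 1, 1), " ".join(["alpha"] * 1000)),
    ]

    coverage_messages = []
    for i in range(100):
        text = "base"
        if i < 9:
            text += " rare9"
        if i < 10:
            text += " rare10"
        coverage_messages.append(
            Message(f"cu{i:03d}", f"cm{i:03d}", datetime(2010, 1, 1), text)
        )

    # comm_small ends at 99 qualifying users (excluded at min_users=100);
    # comm_big has 99 baseline users plus one 30-post user (included) and
    # one 29-post user (excluded), i.e. exactly 100 qualifying.
    n_small, n_big = 99, 99
    user_ids = [f"au{i:03d}" for i in range(n_small + n_big + 2)]
    community = {}
    posts = {}
    for i, uid in enumerate(user_ids):
        if i < n_small:
            community[uid] = "comm_small"
            posts[uid] = 30
        elif i < n_small + n_big:
            community[uid] = "comm_big"
            posts[uid] = 30
        else:
            # boundary users: 29 posts (excluded) and 30 posts (included)
            community[uid] = "comm_big"
            posts[uid] = 29 if i == n_small + n_big else 30
    features = pd.DataFrame(
        {"f": np.linspace(0.0, 1.0, len(user_ids))}, index=user_ids
    )
    return {
        "word_corpus": MessageCorpus(word_messages),
        "coverage_corpus": MessageCorpus(coverage_messages),
        "community_map": pd.Series(community),
        "posts_per_user": pd.Series(posts, dtype=float),
        "user_features": features,
    }
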