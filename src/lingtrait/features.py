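"""Open-vocabulary language features: n-grams, collocations, and topic usage.

Three feature families are produced from a corpus:

* relative frequencies of 1–3-grams (per user, normalized within each n-gram
  order by the user's pre-filter total of that order),
* the same n-grams binarized (used at least once vs. never), and
* topic usage, composed from a word→topic weight lexicon and the user's
  unigram relative frequencies via p(topic|user) = Σ_w p(topic|w)·p(w|user).

Multi-word phrases are retained only when their pointwise mutual information
exceeds a per-gap threshold (collocation filter), and every feature must be
used by a minimum fraction of users (coverage filter) to exclude rare,
idiosyncratic language.  N-grams never cross message boundaries.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from math import log2
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import MessageCorpus, filter_users_by_word_count

__all__ = [
    "FeatureMatrix",
    "TopicLexicon",
    "UserNgramCounts",
    "extract_ngrams",
    "collocation_filter",
    "coverage_filter",
    "relative_frequencies",
    "binarize",
    "topic_usage",
    "FeaturePipeline",
]

logger = logging.getLogger(__name__)

NGram = tuple[str, ...]


def feature_name(ngram: NGram) -> str:
    return " ".join(ngram)


@dataclass
class FeatureMatrix:
    """Rows (users or communities) × named features.

    ``encoding`` is one of ``relfreq``, ``binary``, ``topic``.
    """

    values: pd.DataFrame
    encoding: str

    VALID_ENCODINGS = ("relfreq", "binary", "topic")

    def __post_init__(self) -> None:
        if self.encoding not in self.VALID_ENCODINGS:
            raise ValueError(f"unknown encoding {self.encoding!r}")

    @property
    def row_ids(self) -> list:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def user_coverage(self) -> pd.Series:
        """Fraction of rows with a nonzero value, per feature."""
        return (self.values != 0).mean(axis=0)


@dataclass
class UserNgramCounts:
    """Per-user n-gram counts plus per-order totals (computed pre-filter)."""

    counts: dict[str, Counter]
    totals: dict[str, dict[int, int]]
    n_max: int

    @property
    def user_ids(self) -> list[str]:
        return list(self.counts)

    def pooled(self) -> tuple[Counter, dict[int, int]]:
        """Corpus-pooled counts and per-order totals, summed over users."""
        pooled: Counter = Counter()
        totals: dict[int, int] = {n: 0 for n in range(1, self.n_max + 1)}
        for uid, cnt in self.counts.items():
            pooled.update(cnt)
            for n, t in self.totals[uid].items():
                totals[n] += t
        return pooled, totals

    def document_frequency(self) -> Counter:
        """Number of users using each n-gram at least once."""
        df: Counter = Counter()
        for cnt in self.counts.values():
            df.update(cnt.keys())
        return df


def _message_ngrams(tokens: Sequence[str], n_max: int) -> Iterable[NGram]:
    for n in range(1, n_max + 1):
        for i in range(len(tokens) - n + 1):
            yield tuple(tokens[i : i + n])


def extract_ngrams(
    corpus: MessageCorpus,
    n_max: int = 3,
    vocabulary: set[NGram] | None = None,
) -> UserNgramCounts:
    """Count contiguous 1..n_max-grams per user.

    Phrases never span message boundaries: two consecutive one-token
    messages contribute no bigram.  When ``vocabulary`` is given only those
    n-grams are stored, but the per-order totals still count everything, so
    relative frequencies keep their pre-filter denominators.
    """
    if n_max not in (1, 2, 3):
        raise ValueError("n_max must be 1, 2, or 3")
    counts: dict[str, Counter] = {}
    totals: dict[str, dict[int, int]] = {}
    for uid, msg_tokens in corpus.iter_user_tokens():
        cnt: Counter = Counter()
        tot = {n: 0 for n in range(1, n_max + 1)}
        for tokens in msg_tokens:
            for gram in _message_ngrams(tokens, n_max):
                tot[len(gram)] += 1
                if vocabulary is None or gram in vocabulary:
                    cnt[gram] += 1
        counts[uid] = cnt
        totals[uid] = tot
    return UserNgramCounts(counts=counts, totals=totals, n_max=n_max)


def pmi(
    ngram: NGram,
    pooled: Mapping[NGram, int],
    order_totals: Mapping[int, int],
) -> float:
    """Pointwise mutual information of a phrase against its unigrams.

    PMI = log2[ p(phrase) / Π p(w_i) ], with p(phrase) the phrase count over
    all phrases of that order and p(w_i) the unigram count over all tokens.
    """
    n = len(ngram)
    p_phrase = pooled[ngram] / order_totals[n]
    denom = 1.0
    for w in ngram:
        denom *= pooled[(w,)] / order_totals[1]
    return log2(p_phrase / denom)


def collocation_filter(
    pooled: Mapping[NGram, int],
    order_totals: Mapping[int, int],
    theta: float = 3.0,
) -> set[NGram]:
    """Retain phrases whose PMI ≥ theta·(n−1); unigrams are always kept.

    Phrases with a zero-probability component (a unigram never seen on its
    own, e.g. only sentinel collisions) are dropped and logged.
    """
    retained: set[NGram] = set()
    dropped_zero = 0
    for gram, count in pooled.items():
        n = len(gram)
        if n == 1:
            retained.add(gram)
            continue
        if count <= 0 or any(pooled.get((w,), 0) <= 0 for w in gram):
            dropped_zero += 1
            continue
        if pmi(gram, pooled, order_totals) >= theta * (n - 1):
            retained.add(gram)
    if dropped_zero:
        logger.info("collocation_filter: dropped %d zero-probability phrases",
                    dropped_zero)
    return retained


def coverage_filter(
    document_frequency: Mapping[NGram, int],
    n_users: int,
    min_user_frac: float = 0.10,
) -> set[NGram]:
    """Keep features used by at least ``min_user_frac`` of users (inclusive)."""
    if not 0 <= min_user_frac <= 1:
        raise ValueError("min_user_frac must be in [0, 1]")
    return {
        g for g, df in document_frequency.items() if df / n_users >= min_user_frac
    }


def relative_frequencies(
    user_counts: UserNgramCounts,
    features: Iterable[NGram] | None = None,
) -> FeatureMatrix:
    """Per-user relative frequencies, normalized within each n-gram order.

    The denominator is the user's *pre-filter* total count of that order, so
    rows stay comparable regardless of vocabulary pruning: the retained mass
    of a row sums to ≤ 1, with equality when nothing was filtered.
    """
    if features is None:
        feats = sorted({g for c in user_counts.counts.values() for g in c})
    else:
        feats = sorted(set(features))
    cols = [feature_name(g) for g in feats]
    col_of = {g: j for j, g in enumerate(feats)}
    data = np.zeros((len(user_counts.counts), len(feats)))
    warned = False
    for i, (uid, cnt) in enumerate(user_counts.counts.items()):
        tot = user_counts.totals[uid]
        for gram, c in cnt.items():
            j = col_of.get(gram)
            if j is None or not c:
                continue
            denom = tot.get(len(gram), 0)
            if denom == 0:
                if not warned:
                    warnings.warn(
                        f"user {uid!r} has zero total at order "
                        f"{len(gram)}; row left at zero"
                    )
                    warned = True
                continue
            data[i, j] = c / denom
    df = pd.DataFrame(data, index=list(user_counts.counts), columns=cols)
    return FeatureMatrix(values=df, encoding="relfreq")


def binarize(matrix: FeatureMatrix) -> FeatureMatrix:
    """Map any positive value to 1 (used at least once), else 0."""
    if matrix.encoding != "relfreq":
        raise ValueError("binarize expects a relfreq matrix")
    return FeatureMatrix(
        values=(matrix.values > 0).astype(float), encoding="binary"
    )


@dataclass
class TopicLexicon:
    """Word→topic weights, probability-like p(topic|term).

    Stored long-form with columns ``term``, ``topic_id``, ``weight``.
    For each term the weights across topics should sum to at most 1 (plus
    numerical tolerance).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"term", "topic_id", "weight"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"topic lexicon missing columns: {sorted(missing)}")
        if (self.table["weight"] < 0).any():
            raise ValueError("topic lexicon weights must be non-negative")
        sums = self.table.groupby("term")["weight"].sum()
        if (sums > 1 + 1e-6).any():
            bad = sums[sums > 1 + 1e-6].index[:3].tolist()
            raise ValueError(
                f"per-term topic weights exceed 1 for terms like {bad}"
            )

    @property
    def topic_ids(self) -> list:
        return sorted(self.table["topic_id"].unique().tolist())

    def weight_matrix(self, terms: Sequence[str]) -> pd.DataFrame:
        """terms × topics weight matrix restricted to ``terms`` (zeros elsewhere)."""
        sub = self.table[self.table["term"].isin(terms)]
        mat = sub.pivot_table(
            index="term", columns="topic_id", values="weight", fill_value=0.0,
            aggfunc="sum",
        )
        return mat.reindex(index=terms, columns=self.topic_ids, fill_value=0.0)


def topic_usage(
    unigram_matrix: FeatureMatrix, lexicon: TopicLexicon
) -> FeatureMatrix:
    """Compose p(topic|user) = Σ_terms p(topic|term)·relfreq(term|user)."""
    if unigram_matrix.encoding != "relfreq":
        raise ValueError("topic_usage expects a relfreq unigram matrix")
    terms = unigram_matrix.feature_names
    W = lexicon.weight_matrix(terms)
    if (W.values == 0).all():
        warnings.warn("no topic-lexicon term overlaps the corpus vocabulary; "
                      "topic usage is all zero")
    usage = unigram_matrix.values.values @ W.values
    df = pd.DataFrame(
        usage,
        index=unigram_matrix.values.index,
        columns=[f"topic_{t}" for t in W.columns],
    )
    return FeatureMatrix(values=df, encoding="topic")


class FeaturePipeline:
    """Fit a feature vocabulary on a corpus, then transform corpora to the
    three feature families with that fixed vocabulary.

    The fitted vocabulary is what makes scores comparable across corpora
    (e.g., time bins for test–retest, or community-aggregated matrices):
    ``transform`` always emits the same columns in the same order.

    Parameters
    ----------
    n_max : maximum phrase length (1–3).
    min_words : per-user inclusion threshold on total tokens (inclusive),
        applied during ``fit`` and optionally during ``transform``.
    min_coverage : minimum fraction of users that must use a feature.
    pmi_theta : per-gap collocation threshold; a phrase of n words is kept
        when its PMI ≥ theta·(n−1).
    topic_lexicon : optional word→topic lexicon; when given, ``transform``
        also emits the topic family.
    """

    def __init__(
        self,
        n_max: int = 3,
        min_words: int = 1000,
        min_coverage: float = 0.10,
        pmi_theta: float = 3.0,
        topic_lexicon: TopicLexicon | None = None,
    ) -> None:
        self.n_max = n_max
        self.min_words = min_words
        self.min_coverage = min_coverage
        self.pmi_theta = pmi_theta
        self.topic_lexicon = topic_lexicon
        self.vocabulary_: list[NGram] | None = None

    def fit(self, corpus: MessageCorpus) -> "FeaturePipeline":
        corpus = filter_users_by_word_count(corpus, self.min_words)
        counts = extract_ngrams(corpus, self.n_max)
        pooled, order_totals = counts.pooled()
        covered = coverage_filter(
            counts.document_frequency(), len(counts.counts), self.min_coverage
        )
        collocated = collocation_filter(pooled, order_totals, self.pmi_theta)
        self.vocabulary_ = sorted(covered & collocated)
        if not self.vocabulary_:
            raise ValueError("no feature survived the coverage and "
                             "collocation filters")
        return self

    def transform(
        self, corpus: MessageCorpus, apply_word_filter: bool = False
    ) -> dict[str, FeatureMatrix]:
        if self.vocabulary_ is None:
            raise RuntimeError("pipeline is not fitted")
        if apply_word_filter:
            corpus = filter_users_by_word_count(corpus, self.min_words)
        counts = extract_ngrams(
            corpus, self.n_max, vocabulary=set(self.vocabulary_)
        )
        relfreq = relative_frequencies(counts, self.vocabulary_)
        out = {"relfreq": relfreq, "binary": binarize(relfreq)}
        if self.topic_lexicon is not None:
            unigrams = [g for g in self.vocabulary_ if len(g) == 1]
            uni = FeatureMatrix(
                values=relfreq.values[[feature_name(g) for g in unigrams]],
                encoding="relfreq",
            )
            # topic columns are keyed by raw terms, not joined names
            uni.values.columns = [g[0] for g in unigrams]
            out["topic"] = topic_usage(uni, self.topic_lexicon)
        return out

    def fit_transform(self, corpus: MessageCorpus) -> dict[str, FeatureMatrix]:
        return self.fit(corpus).transform(corpus, apply_word_filter=True)
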