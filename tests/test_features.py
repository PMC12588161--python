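"""N-gram extraction, collocation/coverage filtering, and feature matrices."""

import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from lingtrait.corpus import Message, MessageCorpus
from lingtrait.features import (
    FeatureMatrix,
    FeaturePipeline,
    TopicLexicon,
    binarize,
    collocation_filter,
    coverage_filter,
    extract_ngrams,
    pmi,
    relative_frequencies,
    topic_usage,
)


def corpus_from_texts(user_texts: dict[str, list[str]]) -> MessageCorpus:
    msgs = []
    i = 0
    for uid, texts in user_texts.items():
        for t in texts:
            msgs.append(Message(uid, f"m{i}", None, t))
            i += 1
    return MessageCorpus(msgs)


# ---------------------------------------------------------------- n-grams


def test_extract_ngrams_enumeration():
    corpus = corpus_from_texts({"u": ["a b a"]})
    counts = extract_ngrams(corpus, n_max=2)
    c = counts.counts["u"]
    assert c == Counter(
        {("a",): 2, ("b",): 1, ("a", "b"): 1, ("b", "a"): 1}
    )
    assert counts.totals["u"] == {1: 3, 2: 2}


def test_ngrams_do_not_span_messages():
    corpus = corpus_from_texts({"u": ["a", "b"]})
    counts = extract_ngrams(corpus, n_max=2)
    assert ("a", "b") not in counts.counts["u"]
    assert counts.totals["u"][2] == 0


def test_unigrams_only():
    corpus = corpus_from_texts({"u": ["a b c"]})
    counts = extract_ngrams(corpus, n_max=1)
    assert all(len(g) == 1 for g in counts.counts["u"])


# ---------------------------------------------------------- collocations


def test_pmi_hand_example():
    """100 tokens, 'new'=10, 'york'=5, bigram 5 of 99 → PMI ≈ 3.34,
    retained at theta=3."""
    pooled = Counter({("new",): 10, ("york",): 5, ("new", "york"): 5})
    totals = {1: 100, 2: 99}
    value = pmi(("new", "york"), pooled, totals)
    expected = math.log2((5 / 99) / ((10 / 100) * (5 / 100)))
    assert value == pytest.approx(expected)
    assert value == pytest.approx(3.3361, abs=1e-3)
    kept = collocation_filter(pooled, totals, theta=3.0)
    assert ("new", "york") in kept


def test_independent_pair_has_zero_pmi_and_is_dropped():
    # p(phrase) = p(a)p(b) exactly: a=10/100, b=20/100, phrase=2/100
    pooled = Counter({("a",): 10, ("b",): 20, ("a", "b"): 2})
    totals = {1: 100, 2: 100}
    assert pmi(("a", "b"), pooled, totals) == pytest.approx(0.0)
    kept = collocation_filter(pooled, totals, theta=3.0)
    assert ("a", "b") not in kept
    assert ("a",) in kept  # unigrams always retained


def test_vacuous_theta_retains_all_observed_phrases():
    pooled = Counter({("a",): 50, ("b",): 50, ("a", "b"): 1})
    totals = {1: 100, 2: 99}
    kept = collocation_filter(pooled, totals, theta=-math.inf)
    assert ("a", "b") in kept


# -------------------------------------------------------------- coverage


def test_coverage_boundary_inclusive():
    """9 of 100 users is dropped, 10 of 100 retained at 10%."""
    df = Counter({("rare9",): 9, ("rare10",): 10, ("base",): 100})
    kept = coverage_filter(df, n_users=100, min_user_frac=0.10)
    assert ("rare9",) not in kept
    assert ("rare10",) in kept


def test_coverage_zero_keeps_everything():
    df = Counter({("a",): 1, ("b",): 99})
    assert coverage_filter(df, 100, 0.0) == {("a",), ("b",)}


# ----------------------------------------------------- relative frequency


def test_relfreq_arithmetic_and_conservation():
    corpus = corpus_from_texts({"u": ["a a b b"], "v": ["a c"]})
    counts = extract_ngrams(corpus, n_max=1)
    fm = relative_frequencies(counts)
    assert fm.values.loc["u", "a"] == pytest.approx(0.5)
    assert fm.values.loc["u", "b"] == pytest.approx(0.5)
    assert fm.values.loc["u", "c"] == 0.0
    # unfiltered rows conserve mass exactly
    assert fm.values.sum(axis=1).tolist() == pytest.approx([1.0, 1.0])


def test_relfreq_denominator_is_prefilter_total():
    """Dropping a feature shrinks the row sum below 1; the denominator
    stays the user's full order total."""
    corpus = corpus_from_texts({"u": ["a a a b"]})
    counts = extract_ngrams(corpus, n_max=1)
    fm = relative_frequencies(counts, features=[("a",)])
    assert fm.values.loc["u", "a"] == pytest.approx(0.75)
    assert fm.values.loc["u"].sum() < 1


def test_binarize_values_and_idempotence():
    df = pd.DataFrame({"a": [0.5, 0.0], "b": [0.01, 0.99]}, index=["u", "v"])
    fm = FeatureMatrix(values=df, encoding="relfreq")
    b = binarize(fm)
    assert set(np.unique(b.values.values)) <= {0.0, 1.0}
    assert b.values.loc["u", "a"] == 1
    assert b.values.loc["v", "a"] == 0
    b.encoding = "relfreq"  # re-apply on its own output
    assert binarize(b).values.equals(b.values)


# ------------------------------------------------------------------ topics


def test_topic_usage_single_term():
    lex = TopicLexicon(
        table=pd.DataFrame(
            {"term": ["love"], "topic_id": [1], "weight": [1.0]}
        )
    )
    fm = FeatureMatrix(
        values=pd.DataFrame({"love": [0.2]}, index=["u"]), encoding="relfreq"
    )
    usage = topic_usage(fm, lex)
    assert usage.values.loc["u", "topic_1"] == pytest.approx(0.2)


def test_topic_usage_matches_bruteforce_summation():
    """Two terms × two topics with fractional weights vs. explicit loops."""
    lex_rows = [
        ("love", 1, 0.7),
        ("love", 2, 0.3),
        ("hate", 1, 0.1),
        ("hate", 2, 0.9),
    ]
    lex = TopicLexicon(
        table=pd.DataFrame(lex_rows, columns=["term", "topic_id", "weight"])
    )
    vals = pd.DataFrame(
        {"love": [0.2, 0.05], "hate": [0.01, 0.3]}, index=["u", "v"]
    )
    fm = FeatureMatrix(values=vals, encoding="relfreq")
    usage = topic_usage(fm, lex)
    for user in vals.index:
        for topic in (1, 2):
            expected = sum(
                w * vals.loc[user, term]
                for term, t, w in lex_rows
                if t == topic
            )
            assert usage.values.loc[user, f"topic_{topic}"] == pytest.approx(
                expected
            )


def test_topic_usage_full_assignment_conserves_mass():
    lex = TopicLexicon(
        table=pd.DataFrame(
            {"term": ["a", "b"], "topic_id": [1, 1], "weight": [1.0, 1.0]}
        )
    )
    vals = pd.DataFrame({"a": [0.4], "b": [0.3]}, index=["u"])
    usage = topic_usage(FeatureMatrix(values=vals, encoding="relfreq"), lex)
    assert usage.values.loc["u"].sum() == pytest.approx(0.7)


def test_topic_lexicon_rejects_overweight_terms():
    with pytest.raises(ValueError, match="exceed 1"):
        TopicLexicon(
            table=pd.DataFrame(
                {"term": ["a", "a"], "topic_id": [1, 2], "weight": [0.8, 0.5]}
            )
        )


# ------------------------------------------------- pipeline-level checks


def brute_force_relfreq(corpus: MessageCorpus, n_max: int) -> pd.DataFrame:
    """Independent oracle: nested loops over messages, no shared code with
    the counting path beyond the tokenizer."""
    from lingtrait.corpus import tokenize

    users: dict[str, dict] = {}
    for msg in corpus:
        u = users.setdefault(msg.user_id, {"counts": {}, "totals": {}})
        toks = tokenize(msg.text)
        for n in range(1, n_max + 1):
            for i in range(len(toks) - n + 1):
                gram = " ".join(toks[i : i + n])
                u["counts"][gram] = u["counts"].get(gram, 0) + 1
                u["totals"][n] = u["totals"].get(n, 0) + 1
    all_feats = sorted({g for u in users.values() for g in u["counts"]})
    rows = {}
    for uid, u in users.items():
        row = {}
        for g in all_feats:
            n = g.count(" ") + 1
            row[g] = u["counts"].get(g, 0) / u["totals"][n] if u["totals"].get(n) else 0.0
        rows[uid] = row
    return pd.DataFrame.from_dict(rows, orient="index")[all_feats]


def test_pipeline_matches_bruteforce_oracle(small_sim):
    users = small_sim.ground_truth.users["user_id"].tolist()[:8]
    corpus = small_sim.corpus.subset_users(users)
    counts = extract_ngrams(corpus, n_max=3)
    fm = relative_frequencies(counts)
    oracle = brute_force_relfreq(corpus, n_max=3)
    oracle = oracle.loc[fm.values.index, fm.values.columns]
    np.testing.assert_allclose(fm.values.values, oracle.values, atol=1e-12)


def test_filters_are_permutation_invariant(small_sim):
    users = small_sim.ground_truth.users["user_id"].tolist()[:10]
    corpus_a = small_sim.corpus.subset_users(users)
    # rebuild with messages in reverse order
    corpus_b = MessageCorpus(list(reversed(corpus_a.messages)))
    for corpus, out in ((corpus_a, {}), (corpus_b, {})):
        counts = extract_ngrams(corpus, n_max=2)
        pooled, totals = counts.pooled()
        out["cov"] = coverage_filter(counts.document_frequency(), 10, 0.3)
        out["col"] = collocation_filter(pooled, totals, 3.0)
    ca, ta = extract_ngrams(corpus_a, 2).pooled()
    cb, tb = extract_ngrams(corpus_b, 2).pooled()
    assert ca == cb and ta == tb
    assert coverage_filter(
        extract_ngrams(corpus_a, 2).document_frequency(), 10, 0.3
    ) == coverage_filter(
        extract_ngrams(corpus_b, 2).document_frequency(), 10, 0.3
    )
    assert collocation_filter(ca, ta, 3.0) == collocation_filter(cb, tb, 3.0)


def test_pipeline_deterministic(small_sim):
    users = small_sim.ground_truth.users["user_id"].tolist()[:30]
    corpus = small_sim.corpus.subset_users(users)
    pipe1 = FeaturePipeline(min_words=0, min_coverage=0.2)
    pipe2 = FeaturePipeline(min_words=0, min_coverage=0.2)
    f1 = pipe1.fit_transform(corpus)
    f2 = pipe2.fit_transform(corpus)
    for key in f1:
        pd.testing.assert_frame_equal(f1[key].values, f2[key].values)
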