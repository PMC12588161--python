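"""Feature selection, per-family PCA, ridge fitting, evaluation, retest."""

from datetime import datetime

import numpy as np
import pandas as pd
import pytest

from lingtrait.corpus import Message, MessageCorpus
from lingtrait.features import FeatureMatrix, FeaturePipeline
from lingtrait.synthetic import TIME_BINS
from lingtrait.trait_model import (
    SelectionConfig,
    TraitModel,
    evaluate,
    fit_family_pca,
    fit_trait_model,
    predict_trait,
    select_features,
)
from lingtrait.trait_model import test_retest as retest_reliability


def _family(rng, n=200, p=10, informative=0, noise=1.0, index=None):
    X = rng.normal(size=(n, p))
    y = X[:, :informative].sum(axis=1) if informative else rng.normal(size=n)
    y = y + noise * rng.normal(size=n) if informative else y
    idx = index or [f"u{i}" for i in range(n)]
    df = pd.DataFrame(X, columns=[f"f{j}" for j in range(p)], index=idx)
    return FeatureMatrix(values=df, encoding="relfreq"), pd.Series(y, index=idx)


# ----------------------------------------------------------- selection


def test_select_vacuous_threshold_keeps_all(rng):
    fm, y = _family(rng)
    cfg = SelectionConfig(univariate_p_threshold=1.0)
    assert select_features(fm, y, cfg) == fm.feature_names


def test_select_keeps_exact_copy_drops_permuted(rng):
    n = 1000
    y = pd.Series(rng.normal(size=n), index=[f"u{i}" for i in range(n)])
    shuffled = rng.permutation(y.to_numpy())
    df = pd.DataFrame(
        {"copy": y.to_numpy(), "shuffled": shuffled,
         "noise": rng.normal(size=n)},
        index=y.index,
    )
    fm = FeatureMatrix(values=df, encoding="relfreq")
    selected = select_features(fm, y, SelectionConfig())
    assert "copy" in selected
    assert "shuffled" not in selected


def test_select_nothing_raises(rng):
    fm, y = _family(rng, n=50, p=3)
    cfg = SelectionConfig(univariate_p_threshold=1e-30)
    with pytest.raises(ValueError, match="looser"):
        select_features(fm, y, cfg)


# ----------------------------------------------------------------- PCA


def test_pca_component_cap_is_fraction_of_n(rng):
    X = pd.DataFrame(rng.normal(size=(200, 50)))
    tr = fit_family_pca(X, SelectionConfig(pca_fraction=0.10))
    assert tr.k == 20


def test_pca_rank_bound(rng):
    X = pd.DataFrame(rng.normal(size=(200, 5)))
    tr = fit_family_pca(X, SelectionConfig(pca_fraction=0.10))
    assert tr.k == 5


def test_pca_full_reconstruction(rng):
    X = pd.DataFrame(rng.normal(size=(30, 4)))
    tr = fit_family_pca(X, SelectionConfig(pca_fraction=1.0))
    z = (X.to_numpy() - tr.mean) / tr.std
    comps_std = tr.transform(X)
    comps = comps_std * tr.comp_std + tr.comp_mean
    np.testing.assert_allclose(comps @ tr.components, z, atol=1e-8)


# ------------------------------------------------------------- fitting


def test_noiseless_linear_recovery(rng):
    n = 500
    fm, y = _family(rng, n=n, p=10, informative=3, noise=0.0)
    train, test = fm.values.index[:400], fm.values.index[400:]
    fam_tr = {"f": FeatureMatrix(values=fm.values.loc[train],
                                 encoding="relfreq")}
    fam_te = {"f": FeatureMatrix(values=fm.values.loc[test],
                                 encoding="relfreq")}
    model = fit_trait_model(fam_tr, y.loc[train],
                            SelectionConfig(seed=1, ridge_alpha_grid=(0.01, 1.0)))
    pred = predict_trait(model, fam_te)
    r = np.corrcoef(pred, y.loc[test])[0, 1]
    assert r >= 0.99


def test_row_duplication_invariance_at_matched_penalty(rng):
    fm, y = _family(rng, n=100, p=6, informative=2, noise=0.5)
    dup_vals = pd.concat([fm.values, fm.values.set_axis(
        [f"{i}_dup" for i in fm.values.index])])
    dup_y = pd.concat([y, y.set_axis([f"{i}_dup" for i in y.index])])
    cfg = SelectionConfig(seed=0)
    m1 = fit_trait_model({"f": fm}, y, cfg, fixed_alpha=10.0)
    m2 = fit_trait_model(
        {"f": FeatureMatrix(values=dup_vals, encoding="relfreq")},
        dup_y, cfg, fixed_alpha=20.0,
    )
    p1 = predict_trait(m1, {"f": fm})
    p2 = predict_trait(m2, {"f": fm})
    np.testing.assert_allclose(p1.to_numpy(), p2.to_numpy(), atol=1e-8)


def test_huge_penalty_predicts_training_mean(rng):
    fm, y = _family(rng, n=100, p=5, informative=2)
    model = fit_trait_model({"f": fm}, y, SelectionConfig(seed=0),
                            fixed_alpha=1e12)
    pred = predict_trait(model, {"f": fm})
    np.testing.assert_allclose(pred, y.mean(), atol=1e-6)


def test_model_fit_depends_only_on_training_rows(rng):
    """Rows outside the training index cannot influence the fitted model."""
    fm, y = _family(rng, n=120, p=6, informative=2)
    train = fm.values.index[:100]
    fam_a = {"f": FeatureMatrix(values=fm.values.loc[train].copy(),
                                encoding="relfreq")}
    m1 = fit_trait_model(fam_a, y.loc[train], SelectionConfig(seed=5))
    # perturb the held-out rows, refit on the same training rows
    fm.values.iloc[100:] += 100.0
    fam_b = {"f": FeatureMatrix(values=fm.values.loc[train].copy(),
                                encoding="relfreq")}
    m2 = fit_trait_model(fam_b, y.loc[train], SelectionConfig(seed=5))
    assert m1.to_json() == m2.to_json()


def test_fit_reproducible_byte_for_byte(rng):
    fm, y = _family(rng, n=80, p=6, informative=2)
    cfg = SelectionConfig(seed=7)
    m1 = fit_trait_model({"f": fm}, y, cfg)
    m2 = fit_trait_model({"f": fm}, y, cfg)
    assert m1.to_json() == m2.to_json()


def test_serialization_round_trip(rng, tmp_path):
    fm, y = _family(rng, n=80, p=6, informative=2)
    model = fit_trait_model({"f": fm}, y, SelectionConfig(seed=2))
    path = tmp_path / "model.json"
    model.save(path)
    loaded = TraitModel.load(path)
    assert loaded.to_json() == model.to_json()
    p1 = predict_trait(model, {"f": fm})
    p2 = predict_trait(loaded, {"f": fm})
    np.testing.assert_allclose(p1, p2, atol=0)


# ---------------------------------------------------------- prediction


def test_predict_reproduces_in_sample_fit(rng):
    fm, y = _family(rng, n=100, p=8, informative=3)
    model = fit_trait_model({"f": fm}, y, SelectionConfig(seed=0))
    pred1 = predict_trait(model, {"f": fm})
    pred2 = predict_trait(model, {"f": fm})
    pd.testing.assert_series_equal(pred1, pred2)


def test_identical_rows_identical_scores(rng):
    fm, y = _family(rng, n=100, p=5, informative=2)
    model = fit_trait_model({"f": fm}, y, SelectionConfig(seed=0))
    twin = fm.values.iloc[[0, 0]].set_axis(["a", "b"])
    pred = predict_trait(model, {"f": FeatureMatrix(values=twin,
                                                    encoding="relfreq")})
    assert pred["a"] == pred["b"]


def test_predict_refuses_mostly_missing_features(rng):
    fm, y = _family(rng, n=100, p=10, informative=5, noise=0.1)
    model = fit_trait_model({"f": fm}, y, SelectionConfig(seed=0))
    selected = model.families["f"].feature_names
    keep = selected[: max(1, len(selected) // 3)]
    partial = fm.values[keep]
    with pytest.raises(ValueError, match="refusing"):
        predict_trait(
            model, {"f": FeatureMatrix(values=partial, encoding="relfreq")}
        )


# ---------------------------------------------------------- evaluation


def test_evaluate_identities(rng):
    y = pd.Series(rng.normal(size=50))
    perfect = evaluate(y, y)
    assert perfect.mse == 0 and perfect.r == pytest.approx(1.0)
    flipped = evaluate(-y, y)
    assert flipped.r == pytest.approx(-1.0)
    rep = evaluate(y + 0.1, y, rel_pred=1.0, rel_y=1.0)
    assert rep.r_disattenuated == pytest.approx(rep.r)


def test_evaluate_zero_variance_errors():
    y = pd.Series([1.0, 1.0, 1.0])
    with pytest.raises(ValueError, match="zero variance"):
        evaluate(y, pd.Series([1.0, 2.0, 3.0]))


# --------------------------------------------------------- test-retest


def _retest_setup(small_sim, topic_lexicon):
    users = small_sim.ground_truth.users["user_id"].tolist()[:60]
    corpus = small_sim.corpus.subset_users(users)
    pipe = FeaturePipeline(min_words=0, min_coverage=0.2)
    fams = pipe.fit_transform(corpus)
    scale_y = small_sim.ground_truth.trust.loc[fams["relfreq"].values.index]
    model = fit_trait_model(fams, scale_y, SelectionConfig(seed=3, cv_folds=5))
    return model, corpus, pipe


def test_retest_four_bins_shape_and_range(small_sim, topic_lexicon):
    model, corpus, pipe = _retest_setup(small_sim, topic_lexicon)
    corr = retest_reliability(model, corpus, TIME_BINS, pipe, min_posts_per_bin=3)
    assert corr.shape == (4, 4)
    off_diag = corr.values[np.triu_indices(4, 1)]
    assert len(off_diag) == 6  # four periods → six pairwise correlations
    assert (np.abs(off_diag) <= 1).all()


def test_retest_identical_language_gives_unit_correlation():
    texts = {
        "u1": "love friends great w001 w002 w003",
        "u2": "hate stupid w004 w005 w006 w007",
        "u3": "w001 w004 love hate w002 w005",
        "u4": "w003 w001 w001 great stupid w002",
    }
    msgs = []
    for b, (start, _) in enumerate(TIME_BINS):
        for uid, text in texts.items():
            msgs.append(
                Message(uid, f"{uid}b{b}", start, text)
            )
    corpus = MessageCorpus(msgs)
    pipe = FeaturePipeline(min_words=0, min_coverage=0.2)
    fams = pipe.fit_transform(corpus)
    y = pd.Series([1.0, -1.0, 0.2, -0.1],
                  index=fams["relfreq"].values.index)
    model = fit_trait_model(
        fams, y,
        SelectionConfig(seed=0, cv_folds=2, univariate_p_threshold=1.0,
                        pca_fraction=0.5),
    )
    corr = retest_reliability(model, corpus, TIME_BINS, pipe, min_posts_per_bin=1)
    np.testing.assert_allclose(corr.values, 1.0, atol=1e-10)
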