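"""Differential language analysis (DLA).

Mass-univariate screening: every language feature is regressed (ordinary
least squares) on the outcome with covariate controls, after z-scoring both
the feature and the outcome so the coefficient is a standardized beta.  All
p-values from one analysis run are corrected jointly with the
Benjamini–Hochberg step-up FDR procedure.  The module also covers
dictionary-category associations (LIWC-style trailing-wildcard patterns),
plot-ready word-cloud tables, and the rank-difference moderation display
that compares feature strength across demographic groups.
"""

from __future__ import annotations

import fnmatch
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .features import FeatureMatrix

__all__ = [
    "FeatureAssociation",
    "DlaResult",
    "standardized_association",
    "bh_fdr",
    "run_dla",
    "match_category",
    "category_usage",
    "category_association",
    "wordcloud_table",
    "rank_difference",
]

logger = logging.getLogger(__name__)


@dataclass
class FeatureAssociation:
    feature: str
    beta: float
    ci_low: float
    ci_high: float
    p: float
    q: float | None = None
    freq: float | None = None
    significant: bool | None = None


@dataclass
class DlaResult:
    """Per-feature associations with a single joint FDR correction."""

    table: pd.DataFrame  # columns: feature, beta, ci_low, ci_high, p, q, freq, significant
    alpha: float
    controls: list[str]

    def significant_features(self, sign: str | None = None) -> pd.DataFrame:
        sig = self.table[self.table["significant"]]
        if sign == "pos":
            sig = sig[sig["beta"] > 0]
        elif sign == "neg":
            sig = sig[sig["beta"] < 0]
        elif sign is not None:
            raise ValueError("sign must be 'pos', 'neg', or None")
        return sig.reset_index(drop=True)


def _zscore(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=0)


def standardized_association(
    x: np.ndarray,
    y: np.ndarray,
    covariates: pd.DataFrame | None = None,
    feature: str = "x",
) -> FeatureAssociation:
    """Standardized OLS coefficient of z(y) on z(x) controlling for covariates.

    With no covariates this equals the Pearson correlation of x and y.  The
    95% confidence interval and two-tailed p-value come from the
    coefficient's t distribution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    k_cov = 0 if covariates is None else covariates.shape[1]
    if n < k_cov + 3:
        raise ValueError("too few rows for the number of covariates")
    if x.std(ddof=0) == 0:
        raise ValueError(f"feature {feature!r} has zero variance")
    xz = _zscore(x)
    yz = _zscore(y)
    if covariates is None:
        design = xz[:, None]
    else:
        design = np.column_stack([xz, covariates.to_numpy(dtype=float)])
    design = sm.add_constant(design, prepend=False)
    fit = sm.OLS(yz, design).fit()
    # coefficient on x is the first column
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            f"singular design for feature {feature!r}: covariates are "
            "collinear with the feature or each other"
        )
    ci = fit.conf_int(alpha=0.05)
    return FeatureAssociation(
        feature=feature,
        beta=float(fit.params[0]),
        ci_low=float(ci[0][0]),
        ci_high=float(ci[0][1]),
        p=float(fit.pvalues[0]),
    )


def bh_fdr(
    pvals: np.ndarray | list[float], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up procedure.

    Returns ``(flags, qvals)``: flags are True for every p ≤ p_(k) with
    k = max{i : p_(i) ≤ (i/m)·alpha}; q-values are the monotone step-up
    adjusted p-values.  Empty input yields empty arrays.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([], dtype=bool), np.array([])
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    flags, qvals, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return flags, qvals


def run_dla(
    X: FeatureMatrix,
    y: pd.Series,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
    freqs: pd.Series | None = None,
) -> DlaResult:
    """Screen every feature of ``X`` against ``y``; one joint FDR correction.

    Zero-variance features are skipped with a log record.  ``freqs`` can
    supply corpus frequencies for the word-cloud color bins; by default the
    feature's mean value over rows is used.
    """
    vals = X.values
    idx = vals.index
    y = y.loc[idx]
    if covariates is not None:
        covariates = covariates.loc[idx]
    if freqs is None:
        freqs = vals.mean(axis=0)
    rows = []
    for name in vals.columns:
        col = vals[name].to_numpy(dtype=float)
        if col.std(ddof=0) == 0:
            logger.info("run_dla: skipping zero-variance feature %r", name)
            continue
        assoc = standardized_association(
            col, y.to_numpy(dtype=float), covariates, feature=name
        )
        rows.append(
            {
                "feature": name,
                "beta": assoc.beta,
                "ci_low": assoc.ci_low,
                "ci_high": assoc.ci_high,
                "p": assoc.p,
                "freq": float(freqs[name]),
            }
        )
    table = pd.DataFrame(
        rows, columns=["feature", "beta", "ci_low", "ci_high", "p", "freq"]
    )
    if len(table):
        flags, qvals = bh_fdr(table["p"].to_numpy(), alpha=alpha)
        table["q"] = qvals
        table["significant"] = flags
        # strongest associations first, positives before negatives
        table = (
            table.assign(_sign=np.sign(table["beta"]),
                         _mag=table["beta"].abs())
            .sort_values(["_sign", "_mag"], ascending=[False, False])
            .drop(columns=["_sign", "_mag"])
            .reset_index(drop=True)
        )
    else:
        table["q"] = []
        table["significant"] = []
    controls = [] if covariates is None else list(covariates.columns)
    return DlaResult(table=table, alpha=alpha, controls=controls)


def match_category(pattern_list: list[str], vocabulary: list[str]) -> set[str]:
    """Expand LIWC-style patterns over a vocabulary.

    A trailing ``*`` is a prefix wildcard (``hat*`` matches ``hate`` and
    ``hatin`` but not ``that``); anything else matches exactly.
    """
    matched: set[str] = set()
    for pat in pattern_list:
        if pat.endswith("*"):
            prefix = pat[:-1]
            matched.update(w for w in vocabulary if w.startswith(prefix))
        elif pat in vocabulary:
            matched.add(pat)
    return matched


def category_usage(
    lexicon: dict[str, list[str]], unigrams: FeatureMatrix
) -> pd.DataFrame:
    """Per-user category values: Σ relfreq of matched unigrams."""
    if unigrams.encoding != "relfreq":
        raise ValueError("category extraction expects relfreq unigrams")
    vocab = list(unigrams.values.columns)
    cols = {}
    for cat, patterns in lexicon.items():
        words = match_category(patterns, vocab)
        if not words:
            warnings.warn(f"category {cat!r} matches no corpus word; skipped")
            continue
        cols[cat] = unigrams.values[sorted(words)].sum(axis=1)
    return pd.DataFrame(cols, index=unigrams.values.index)


def category_association(
    lexicon: dict[str, list[str]],
    unigrams: FeatureMatrix,
    y: pd.Series,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> DlaResult:
    """Dictionary-category DLA: category frequencies instead of raw n-grams."""
    usage = category_usage(lexicon, unigrams)
    zero_var = [c for c in usage.columns if usage[c].std(ddof=0) == 0]
    if zero_var:
        warnings.warn(
            f"categories with zero variance skipped: {zero_var}"
        )
        usage = usage.drop(columns=zero_var)
    fm = FeatureMatrix(values=usage, encoding="relfreq")
    return run_dla(fm, y, covariates, alpha=alpha)


def wordcloud_table(
    result: DlaResult,
    sign: str,
    topic_lexicon=None,
    top_k: int | None = None,
) -> pd.DataFrame:
    """Plot-ready table for a word cloud of one sign's significant features.

    Display size is proportional to |beta| with the strongest feature scaled
    to 100; a color bin encodes corpus frequency by terciles (gray = low,
    blue = moderate, red = high).  Topic features additionally list their
    top 15 most prevalent words when a topic lexicon is supplied.
    """
    sig = result.significant_features(sign=sign)
    if top_k is not None:
        sig = sig.iloc[:top_k]
    if sig.empty:
        warnings.warn("no significant features of the requested sign")
        return pd.DataFrame(
            columns=["feature", "beta", "size", "freq", "color", "top_words"]
        )
    mag = sig["beta"].abs()
    size = 100 * mag / mag.max()
    terciles = np.quantile(sig["freq"], [1 / 3, 2 / 3])
    color = np.where(
        sig["freq"] <= terciles[0],
        "gray",
        np.where(sig["freq"] <= terciles[1], "blue", "red"),
    )
    top_words = []
    for feat in sig["feature"]:
        if topic_lexicon is not None and feat.startswith("topic_"):
            tid_raw = feat[len("topic_"):]
            tab = topic_lexicon.table
            tid_col = tab["topic_id"].astype(str)
            sub = tab[tid_col == tid_raw].nlargest(15, "weight")
            top_words.append(" ".join(sub["term"].tolist()))
        else:
            top_words.append("")
    return pd.DataFrame(
        {
            "feature": sig["feature"].to_numpy(),
            "beta": sig["beta"].to_numpy(),
            "size": size.to_numpy(),
            "freq": sig["freq"].to_numpy(),
            "color": color,
            "top_words": top_words,
        }
    )


def rank_difference(
    results: dict[str, DlaResult],
    comparison: str = "mean_of_others",
) -> pd.DataFrame:
    """Moderation display: how much stronger a feature ranks in one group.

    Within each group and sign, significant features are ranked by |beta|
    descending (rank 1 = strongest; ties get the average rank).  The rank
    difference is the comparison rank (the other group's, or the mean of
    the other groups') minus the group's own rank — positive means the
    feature is relatively stronger in this group.  Features absent from a
    group's significant list take the sentinel rank m+1, where m is that
    group's list length.  Color: gray for diff ≤ 0, otherwise a green shade
    linear in the difference, capped at the 95th percentile.
    """
    if len(results) < 2:
        raise ValueError("rank_difference needs at least two groups")
    if comparison not in ("other_group", "mean_of_others"):
        raise ValueError(f"unknown comparison {comparison!r}")
    if comparison == "other_group" and len(results) != 2:
        raise ValueError("'other_group' comparison requires exactly 2 groups")

    # rank tables per (group, sign): feature -> rank
    ranks: dict[str, dict[str, dict[str, float]]] = {}
    list_len: dict[str, dict[str, int]] = {}
    for g, res in results.items():
        ranks[g] = {}
        list_len[g] = {}
        for sign in ("pos", "neg"):
            sig = res.significant_features(sign=sign)
            mags = sig["beta"].abs().to_numpy()
            # descending magnitude; ties averaged
            r = stats.rankdata(-mags, method="average")
            ranks[g][sign] = dict(zip(sig["feature"], r))
            list_len[g][sign] = len(sig)

    rows = []
    groups = list(results)
    for g in groups:
        others = [h for h in groups if h != g]
        for sign in ("pos", "neg"):
            for feat, own_rank in ranks[g][sign].items():
                comp_ranks = []
                for h in others:
                    rh = ranks[h][sign].get(feat)
                    if rh is None:
                        rh = list_len[h][sign] + 1
                        logger.info(
                            "rank_difference: %r absent from group %r (%s); "
                            "sentinel rank %d", feat, h, sign, int(rh)
                        )
                    comp_ranks.append(rh)
                diff = float(np.mean(comp_ranks)) - own_rank
                rows.append(
                    {
                        "group": g,
                        "sign": sign,
                        "feature": feat,
                        "rank": own_rank,
                        "rank_diff": diff,
                    }
                )
    out = pd.DataFrame(rows)
    if out.empty:
        out["color"] = []
        out["shade"] = []
        return out
    pos = out["rank_diff"].clip(lower=0)
    cap = np.percentile(pos[pos > 0], 95) if (pos > 0).any() else 1.0
    cap = cap if cap > 0 else 1.0
    out["shade"] = np.minimum(pos / cap, 1.0)
    out["color"] = np.where(out["rank_diff"] <= 0, "gray", "green")
    return out
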