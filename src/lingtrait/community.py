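"""Community-level aggregation, scoring, and adjusted correlates.

User language features are averaged to communities (mirroring the mean of a
survey sample): users need a minimum number of posts to count, and a
community needs a minimum number of qualifying users to be retained.
Because the trait scorer is affine, scoring the community mean equals the
mean of the members' individual scores — an identity the tests assert.

Community scores are then correlated with outcome tables (health, wellbeing,
socioeconomics, voting …), reporting both the unadjusted product-moment
correlation and a covariate-adjusted standardized beta (trust as the
independent variable), with a joint BH-FDR correction over outcomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .dla import bh_fdr, standardized_association
from .features import FeatureMatrix
from .trait_model import TraitModel, predict_trait

__all__ = [
    "OutcomeTable",
    "aggregate_features",
    "score_communities",
    "respondent_filter",
    "community_correlates",
]


@dataclass
class OutcomeTable:
    """Community × outcome values with per-outcome respondent counts.

    ``n_respondents`` (same shape as ``values``) and ``min_respondents``
    (per outcome) drive :func:`respondent_filter`; ``covariates`` holds
    community-level adjustment columns such as region indicators.
    """

    values: pd.DataFrame
    n_respondents: pd.DataFrame | None = None
    min_respondents: dict[str, int] = field(default_factory=dict)
    covariates: pd.DataFrame | None = None


def aggregate_features(
    X_user: FeatureMatrix,
    community_map: pd.Series,
    posts_per_user: pd.Series,
    min_posts: int = 30,
    min_users: int = 100,
) -> tuple[FeatureMatrix, pd.Series]:
    """Average qualifying users' features within each community.

    Users with fewer than ``min_posts`` posts are dropped (inclusive
    threshold: exactly ``min_posts`` qualifies), then communities with
    fewer than ``min_users`` remaining users are dropped.  Returns the
    community feature matrix and the per-community user count.
    """
    users = X_user.values.index
    mapped = community_map.reindex(users).dropna()
    posts = posts_per_user.reindex(mapped.index)
    qualifying = mapped.index[posts >= min_posts]
    if len(qualifying) == 0:
        raise ValueError("no user meets the minimum post threshold")
    sub = X_user.values.loc[qualifying]
    groups = mapped.loc[qualifying]
    means = sub.groupby(groups).mean()
    counts = groups.value_counts()
    keep = counts.index[counts >= min_users]
    if len(keep) == 0:
        raise ValueError("no community meets the minimum user threshold")
    means = means.loc[means.index.isin(keep)].sort_index()
    counts = counts.loc[means.index]
    return (
        FeatureMatrix(values=means, encoding=X_user.encoding),
        counts.rename("n_users"),
    )


def score_communities(
    model: TraitModel, families: Mapping[str, FeatureMatrix]
) -> pd.Series:
    """Apply the trait model to community-level feature matrices."""
    return predict_trait(model, families, strict=False).rename("trust_score")


def respondent_filter(outcomes: OutcomeTable) -> OutcomeTable:
    """Blank out community–outcome cells with too few respondents.

    An outcome left with no valid cell is dropped with a warning.
    """
    if outcomes.n_respondents is None or not outcomes.min_respondents:
        return outcomes
    values = outcomes.values.copy()
    for col, threshold in outcomes.min_respondents.items():
        if col not in values.columns or threshold <= 0:
            continue
        nr = outcomes.n_respondents[col].reindex(values.index)
        values.loc[nr.fillna(0) < threshold, col] = np.nan
    empty = [c for c in values.columns if values[c].isna().all()]
    if empty:
        warnings.warn(f"outcomes dropped (all cells below threshold): {empty}")
        values = values.drop(columns=empty)
    return OutcomeTable(
        values=values,
        n_respondents=outcomes.n_respondents,
        min_respondents=outcomes.min_respondents,
        covariates=outcomes.covariates,
    )


def community_correlates(
    scores: pd.Series,
    outcomes: OutcomeTable,
    adjust: list[str] | None = None,
    alpha: float = 0.05,
    min_communities: int = 10,
) -> pd.DataFrame:
    """Unadjusted r and covariate-adjusted standardized beta per outcome.

    Trust (the community score) is the independent variable and each
    outcome the dependent variable.  A joint BH-FDR correction is applied
    over all outcomes in the table.  Outcomes observed in fewer than
    ``min_communities`` communities are skipped with a warning.
    """
    adjust = adjust or []
    cov_all = outcomes.covariates
    if adjust and cov_all is None:
        raise ValueError("adjustment requested but the outcome table has no "
                         "covariates")
    rows = []
    for col in outcomes.values.columns:
        yvals = outcomes.values[col]
        common = scores.index.intersection(yvals.dropna().index)
        if len(common) < min_communities:
            warnings.warn(
                f"outcome {col!r} observed in only {len(common)} "
                "communities; skipped"
            )
            continue
        x = scores.loc[common].to_numpy(dtype=float)
        yv = yvals.loc[common].to_numpy(dtype=float)
        r = float(np.corrcoef(x, yv)[0, 1])
        cov = cov_all.loc[common, adjust] if adjust else None
        assoc = standardized_association(x, yv, cov, feature=col)
        rows.append(
            {
                "outcome": col,
                "r": r,
                "beta": assoc.beta,
                "ci_low": assoc.ci_low,
                "ci_high": assoc.ci_high,
                "p": assoc.p,
                "n_communities": len(common),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["outcome", "r", "beta", "ci_low", "ci_high", "p",
                 "n_communities"],
    )
    if len(table):
        flags, qvals = bh_fdr(table["p"].to_numpy(), alpha=alpha)
        table["q"] = qvals
        table["significant"] = flags
    else:
        table["q"] = []
        table["significant"] = []
    return table
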