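"""Survey scale scoring, reliability, disattenuation, and demographic bins.

The generalized-trust score used throughout is the mean of three Likert items
(one reverse-coded, e.g. "I suspect hidden motives in others").  Reliability
is Cronbach's alpha; observed correlations with imperfectly reliable measures
can be corrected for attenuation by dividing by the geometric mean of the two
reliabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScaleDefinition",
    "ScaleScores",
    "score_scale",
    "cronbach_alpha",
    "disattenuate",
    "tercile_indicators",
]


@dataclass(frozen=True)
class ScaleDefinition:
    """Items of a summative scale with reverse flags and response endpoints."""

    item_ids: tuple[str, ...]
    reverse_flags: tuple[bool, ...]
    response_min: float = 1.0
    response_max: float = 5.0

    def __post_init__(self) -> None:
        if not self.item_ids:
            raise ValueError("a scale needs at least one item")
        if len(self.item_ids) != len(self.reverse_flags):
            raise ValueError("item_ids and reverse_flags differ in length")
        if not np.isfinite([self.response_min, self.response_max]).all():
            raise ValueError("response endpoints must be finite")
        if self.response_min >= self.response_max:
            raise ValueError("response_min must be below response_max")


@dataclass
class ScaleScores:
    scores: pd.Series
    reliability: float | None = None


def _recoded_items(
    responses: pd.DataFrame, scale: ScaleDefinition
) -> pd.DataFrame:
    """Reverse-coded item matrix restricted to complete cases."""
    missing_cols = [i for i in scale.item_ids if i not in responses.columns]
    if missing_cols:
        raise KeyError(f"survey table lacks items: {missing_cols}")
    items = responses[list(scale.item_ids)].astype(float)
    n_before = len(items)
    items = items.dropna()
    if len(items) < n_before:
        warnings.warn(
            f"dropped {n_before - len(items)} respondents with missing items"
        )
    for item, rev in zip(scale.item_ids, scale.reverse_flags):
        if rev:
            items[item] = scale.response_min + scale.response_max - items[item]
    return items


def score_scale(
    responses: pd.DataFrame, scale: ScaleDefinition
) -> ScaleScores:
    """Mean of (reverse-coded where flagged) items, complete cases only."""
    items = _recoded_items(responses, scale)
    scores = items.mean(axis=1)
    rel = None
    if len(scale.item_ids) >= 2 and len(items) >= 3:
        try:
            rel = cronbach_alpha(responses, scale)
        except ValueError:
            rel = None
    return ScaleScores(scores=scores, reliability=rel)


def cronbach_alpha(responses: pd.DataFrame, scale: ScaleDefinition) -> float:
    """alpha = k/(k−1) · (1 − Σ item variances / variance of the item sum).

    Computed after reverse-coding, on complete cases, with sample (ddof=1)
    variances.
    """
    k = len(scale.item_ids)
    if k < 2:
        raise ValueError("Cronbach's alpha needs at least 2 items")
    items = _recoded_items(responses, scale)
    if len(items) < 3:
        raise ValueError("Cronbach's alpha needs at least 3 complete "
                         "respondents")
    item_vars = items.var(axis=0, ddof=1)
    total_var = items.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total-score variance; alpha undefined")
    return k / (k - 1) * (1 - item_vars.sum() / total_var)


def disattenuate(r: float, rel_x: float, rel_y: float) -> float:
    """Correct a correlation for unreliability: r / sqrt(rel_x·rel_y).

    Clipped to [−1, 1] with a warning, since sampling error can push the
    corrected value out of range.
    """
    if rel_x <= 0 or rel_y <= 0:
        raise ValueError("reliabilities must be positive")
    out = r / np.sqrt(rel_x * rel_y)
    if abs(out) > 1:
        warnings.warn(
            f"disattenuated correlation {out:.4f} clipped to ±1"
        )
        out = float(np.clip(out, -1.0, 1.0))
    return float(out)


def tercile_indicators(
    ages: pd.Series, mode: str = "paper_bins"
) -> pd.DataFrame:
    """Three age-bin indicator columns (exactly one 1 per respondent).

    ``paper_bins`` uses the life-stage bins ≤18 / 19–23 / ≥24 (pre/early
    college, college-aged, post-college); ``empirical`` splits at the
    sample's own tercile boundaries with ties going to the lower bin.
    """
    ages = ages.astype(float)
    if (ages < 0).any():
        raise ValueError("ages must be non-negative")
    if mode == "paper_bins":
        lo, hi = 18.0, 23.0
    elif mode == "empirical":
        lo, hi = np.quantile(ages.values, [1 / 3, 2 / 3])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    bin1 = ages <= lo
    bin2 = (ages > lo) & (ages <= hi)
    bin3 = ages > hi
    out = pd.DataFrame(
        {
            "age_bin1": bin1.astype(int),
            "age_bin2": bin2.astype(int),
            "age_bin3": bin3.astype(int),
        },
        index=ages.index,
    )
    assert (out.sum(axis=1) == 1).all()
    return out
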