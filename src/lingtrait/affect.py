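"""Message-level affect and the social-language "othering" contrast.

Each message gets an affective score (mean lexicon weight over matched
tokens), z-normalized across the corpus.  Messages are then tagged by word
sets — e.g. "social" messages, and the subsets containing *people* or
*they* — and the mean normalized affect of each subset is contrasted
against the all-message baseline.  A dictionary category can be split into
an othering sub-category and its complement to re-run the association with
trust separately for each part.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .corpus import MessageCorpus, tokenize
from .dla import match_category

__all__ = [
    "message_affect",
    "tag_subsets",
    "subset_contrast",
    "split_category",
]


def message_affect(
    corpus: MessageCorpus,
    lexicon: dict[str, float],
    unmatched: str = "exclude",
) -> pd.Series:
    """Normalized per-message affect.

    Raw score = mean lexicon weight over matched tokens.  Messages with no
    matched token are excluded by default (``unmatched='exclude'``) so they
    cannot dilute the baseline, or set to 0 (``unmatched='zero'``).  Scores
    are then z-normalized across all scored messages.
    """
    if not lexicon:
        raise ValueError("affect lexicon is empty")
    if unmatched not in ("exclude", "zero"):
        raise ValueError("unmatched must be 'exclude' or 'zero'")
    raw = {}
    for msg in corpus:
        weights = [lexicon[t] for t in tokenize(msg.text) if t in lexicon]
        if weights:
            raw[msg.message_id] = float(np.mean(weights))
        elif unmatched == "zero":
            raw[msg.message_id] = 0.0
    if not raw:
        raise ValueError("no message matched the affect lexicon")
    scores = pd.Series(raw, name="affect")
    sd = scores.std(ddof=0)
    if sd == 0:
        raise ValueError("affect scores have zero variance; cannot normalize")
    return (scores - scores.mean()) / sd


def tag_subsets(
    corpus: MessageCorpus, word_sets: dict[str, set[str]]
) -> pd.DataFrame:
    """Boolean message tags: True when any token is in the word set.

    Uses the same tokenizer as feature extraction, so tags line up with
    n-gram features.  Nested word sets yield nested tags.
    """
    rows = {}
    for msg in corpus:
        tokens = set(tokenize(msg.text))
        rows[msg.message_id] = {
            name: bool(tokens & ws) for name, ws in word_sets.items()
        }
    return pd.DataFrame.from_dict(rows, orient="index").reindex(
        [m.message_id for m in corpus]
    )


@dataclass
class SubsetContrast:
    name: str
    n: int
    mean: float
    ci_low: float
    ci_high: float


def subset_contrast(
    scores: pd.Series, tags: pd.DataFrame
) -> pd.DataFrame:
    """Mean normalized affect per tagged subset, with 95% normal CIs.

    The baseline row ``all`` covers every scored message (its mean is 0 by
    normalization).  Subsets of size < 2 get NaN CIs and a warning.
    """
    rows = []

    def _row(name: str, vals: np.ndarray) -> dict:
        n = len(vals)
        mean = float(np.mean(vals)) if n else np.nan
        if n >= 2:
            half = 1.96 * np.std(vals, ddof=1) / np.sqrt(n)
            ci_low, ci_high = mean - half, mean + half
        else:
            warnings.warn(f"subset {name!r} has fewer than 2 messages; "
                          "CI undefined")
            ci_low = ci_high = np.nan
        return {"subset": name, "n": n, "mean": mean,
                "ci_low": ci_low, "ci_high": ci_high}

    rows.append(_row("all", scores.to_numpy(dtype=float)))
    for name in tags.columns:
        ids = tags.index[tags[name].fillna(False)]
        vals = scores.reindex(ids).dropna().to_numpy(dtype=float)
        rows.append(_row(name, vals))
    return pd.DataFrame(rows)


def split_category(
    category: list[str],
    removal: set[str],
    vocabulary: list[str] | None = None,
) -> tuple[list[str], list[str]]:
    """Split a dictionary category into (removal-only, remainder) parts.

    ``category`` is a pattern list (trailing ``*`` = prefix wildcard);
    ``removal`` is a plain token set.  When a vocabulary is given, the
    category is first expanded against it, so wildcard matches are split
    correctly; a warning flags removal words the category does not cover.
    Both returned parts are pattern lists usable in category association,
    and they partition the category's matches.
    """
    if vocabulary is not None:
        matched = match_category(category, vocabulary)
        stray = removal - matched
        if stray:
            warnings.warn(
                f"removal words not matched by the category: {sorted(stray)}"
            )
        return sorted(matched & removal), sorted(matched - removal)
    stray = removal - set(category)
    if stray:
        warnings.warn(
            f"removal words not present in the category: {sorted(stray)}"
        )
    return (
        sorted(set(category) & removal),
        [p for p in category if p not in removal],
    )
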