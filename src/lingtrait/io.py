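"""Readers and writers for the pipeline's file formats.

Everything is UTF-8 plain text: messages as CSV or JSONL, surveys and
feature matrices as CSV (wide and sparse-long variants), lexicons as CSV or
JSON, scale definitions and outcome metadata as YAML, trait models as JSON.
All reader/writer pairs round-trip losslessly.
"""

from __future__ import annotations

import json
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .community import OutcomeTable
from .corpus import Message, MessageCorpus
from .features import FeatureMatrix, TopicLexicon
from .psychometrics import ScaleDefinition

__all__ = [
    "read_messages",
    "write_messages",
    "read_survey",
    "read_scale",
    "read_dictionary_lexicon",
    "read_topic_lexicon",
    "read_affect_lexicon",
    "read_word_set",
    "read_outcomes",
    "read_feature_matrix",
    "write_feature_matrix",
    "write_feature_matrix_long",
    "read_feature_matrix_long",
]

MESSAGE_COLUMNS = ["user_id", "message_id", "created_at", "message"]


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def _parse_timestamp(value) -> datetime | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    ts = pd.Timestamp(value)
    if ts.tzinfo is not None:
        ts = ts.tz_convert("UTC").tz_localize(None)
    return ts.to_pydatetime()


def read_messages(path: str | Path) -> MessageCorpus:
    """Read a message corpus from CSV or JSONL (by file extension).

    Required fields: ``user_id``, ``message_id``, ``created_at``
    (ISO-8601, may be empty), ``message``.
    """
    path = Path(path)
    if path.suffix.lower() in (".jsonl", ".ndjson", ".json"):
        records = []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    records.append(json.loads(line))
                except json.JSONDecodeError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: malformed JSON ({exc.msg})"
                    ) from exc
        df = pd.DataFrame.from_records(records)
    else:
        df = pd.read_csv(path, dtype={"user_id": str, "message_id": str},
                         keep_default_na=False, na_values=[])
    _require_columns(df, MESSAGE_COLUMNS, path)
    messages = [
        Message(
            user_id=str(row.user_id),
            message_id=str(row.message_id),
            created_at=_parse_timestamp(row.created_at),
            text=str(row.message) if row.message is not None else "",
        )
        for row in df.itertuples(index=False)
    ]
    return MessageCorpus(messages)


def write_messages(corpus: MessageCorpus, path: str | Path) -> None:
    rows = [
        {
            "user_id": m.user_id,
            "message_id": m.message_id,
            "created_at": m.created_at.isoformat() if m.created_at else "",
            "message": m.text,
        }
        for m in corpus
    ]
    pd.DataFrame(rows, columns=MESSAGE_COLUMNS).to_csv(path, index=False)


def read_survey(path: str | Path) -> pd.DataFrame:
    """Item-response table: ``respondent_id`` plus one column per item."""
    df = pd.read_csv(path)
    _require_columns(df, ["respondent_id"], path)
    return df.set_index("respondent_id")


def read_scale(path: str | Path) -> ScaleDefinition:
    """Scale definition YAML: items, reverse flags, response endpoints."""
    with open(path, encoding="utf-8") as fh:
        spec = yaml.safe_load(fh)
    for key in ("items", "reverse", "response_min", "response_max"):
        if key not in spec:
            raise ValueError(f"{path}: scale YAML missing key {key!r}")
    return ScaleDefinition(
        item_ids=tuple(spec["items"]),
        reverse_flags=tuple(bool(r) for r in spec["reverse"]),
        response_min=float(spec["response_min"]),
        response_max=float(spec["response_max"]),
    )


def read_dictionary_lexicon(path: str | Path) -> dict[str, list[str]]:
    """Category→patterns lexicon from CSV (category,pattern) or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        return {str(k): [str(p) for p in v] for k, v in data.items()}
    df = pd.read_csv(path)
    _require_columns(df, ["category", "pattern"], path)
    out: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.category), []).append(str(row.pattern))
    return out


def read_topic_lexicon(path: str | Path) -> TopicLexicon:
    df = pd.read_csv(path)
    _require_columns(df, ["term", "topic_id", "weight"], path)
    return TopicLexicon(table=df)


def read_affect_lexicon(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path)
    _require_columns(df, ["term", "weight"], path)
    return dict(zip(df["term"].astype(str), df["weight"].astype(float)))


def read_word_set(path: str | Path) -> set[str]:
    """One token per line."""
    with open(path, encoding="utf-8") as fh:
        return {line.strip() for line in fh if line.strip()}


def read_outcomes(
    path: str | Path, meta_path: str | Path | None = None
) -> OutcomeTable:
    """Outcome table CSV (community_id + outcome columns) plus optional
    metadata YAML with respondent thresholds, covariate columns, and
    per-column log flags."""
    df = pd.read_csv(path)
    _require_columns(df, ["community_id"], path)
    df = df.set_index("community_id")
    min_respondents: dict[str, int] = {}
    covariates = None
    n_respondents = None
    if meta_path is not None:
        with open(meta_path, encoding="utf-8") as fh:
            meta = yaml.safe_load(fh) or {}
        min_respondents = {
            str(k): int(v)
            for k, v in (meta.get("min_respondents") or {}).items()
        }
        cov_cols = meta.get("covariates") or []
        if cov_cols:
            missing = [c for c in cov_cols if c not in df.columns]
            if missing:
                raise ValueError(f"{path}: covariate column(s) {missing} "
                                 "not present")
            covariates = df[cov_cols]
            df = df.drop(columns=cov_cols)
        for col in meta.get("log_transform") or []:
            if col not in df.columns:
                raise ValueError(f"{path}: log_transform column {col!r} "
                                 "not present")
            df[col] = np.log(df[col])
        resp_cols = [c for c in df.columns if c.endswith("__n")]
        if resp_cols:
            n_respondents = df[resp_cols].rename(
                columns=lambda c: c[: -len("__n")]
            )
            df = df.drop(columns=resp_cols)
    return OutcomeTable(
        values=df,
        n_respondents=n_respondents,
        min_respondents=min_respondents,
        covariates=covariates,
    )


def write_feature_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    """Wide CSV: row_id, encoding column comment via header, one column per
    feature.  The encoding travels in a sidecar-free way: first column name
    is ``row_id`` and the encoding is stored as an index name suffix."""
    df = matrix.values.copy()
    df.index.name = f"row_id:{matrix.encoding}"
    df.to_csv(path)


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path, index_col=0)
    name = df.index.name or ""
    if ":" not in name:
        raise ValueError(f"{path}: not a feature-matrix CSV (missing "
                         "row_id:<encoding> header)")
    encoding = name.split(":", 1)[1]
    df.index.name = "row_id"
    df.index = df.index.astype(str)
    return FeatureMatrix(values=df, encoding=encoding)


def write_feature_matrix_long(matrix: FeatureMatrix, path: str | Path) -> None:
    """Sparse long CSV: row_id,feature,value for nonzero cells only."""
    stacked = matrix.values.stack()
    stacked = stacked[stacked != 0]
    out = stacked.rename_axis(["row_id", "feature"]).rename("value")
    header = out.reset_index()
    header.insert(0, "encoding", matrix.encoding)
    header.to_csv(path, index=False)


def read_feature_matrix_long(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path)
    _require_columns(df, ["encoding", "row_id", "feature", "value"], path)
    encoding = df["encoding"].iloc[0] if len(df) else "relfreq"
    wide = df.pivot_table(
        index="row_id", columns="feature", values="value", fill_value=0.0,
        aggfunc="sum",
    )
    wide.index = wide.index.astype(str)
    return FeatureMatrix(values=wide, encoding=encoding)
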