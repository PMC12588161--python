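"""Ridge-regression trait assessment over three language feature families.

The model pipeline, per feature family (relative-frequency n-grams, binary
n-grams, topic usage):

1. univariate screen — keep features whose Pearson correlation with the
   outcome has (uncorrected) p below a threshold, computed on training rows
   only;
2. standardize the survivors and reduce them with PCA, capping the number of
   components at a fraction (default 10%) of the number of training
   observations;
3. standardize the components.

The per-family components are concatenated and fed to ridge regression whose
penalty is chosen by seeded k-fold cross-validated MSE over a log grid.
Evaluation reports MSE, the product-moment correlation, and its
disattenuated version given the reliabilities of prediction and criterion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold

from .corpus import MessageCorpus
from .features import FeatureMatrix, FeaturePipeline
from .psychometrics import disattenuate

__all__ = [
    "SelectionConfig",
    "FamilyTransform",
    "TraitModel",
    "EvalReport",
    "select_features",
    "fit_family_pca",
    "fit_trait_model",
    "predict_trait",
    "evaluate",
    "test_retest",
]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class SelectionConfig:
    univariate_p_threshold: float = 0.05
    pca_fraction: float = 0.10
    ridge_alpha_grid: tuple[float, ...] = (1.0, 1e1, 1e2, 1e3, 1e4, 1e5)
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.pca_fraction <= 1:
            raise ValueError("pca_fraction must be in (0, 1]")
        if not self.ridge_alpha_grid:
            raise ValueError("ridge_alpha_grid must be non-empty")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")


def select_features(
    X: FeatureMatrix | pd.DataFrame,
    y: pd.Series,
    config: SelectionConfig,
) -> list[str]:
    """Columns with at least a small univariate correlation with ``y``.

    The screen keeps a feature when the two-tailed p-value of its Pearson
    correlation with the outcome (training rows only) is below
    ``config.univariate_p_threshold``, uncorrected.
    """
    vals = X.values if isinstance(X, FeatureMatrix) else X
    yv = y.loc[vals.index].to_numpy(dtype=float)
    n = len(yv)
    xm = vals.to_numpy(dtype=float)
    xs = xm.std(axis=0, ddof=0)
    keep_var = xs > 0
    xc = (xm - xm.mean(axis=0)) / np.where(keep_var, xs, 1.0)
    yz = (yv - yv.mean()) / yv.std(ddof=0)
    r = xc.T @ yz / n
    r = np.clip(r, -0.9999999999, 0.9999999999)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    mask = keep_var & (p < config.univariate_p_threshold)
    selected = [c for c, m in zip(vals.columns, mask) if m]
    if not selected:
        raise ValueError(
            "no feature passed the univariate screen; consider a looser "
            "univariate_p_threshold"
        )
    return selected


@dataclass
class FamilyTransform:
    """Frozen per-family projection: standardize → PCA → standardize."""

    feature_names: list[str]
    mean: np.ndarray
    std: np.ndarray
    components: np.ndarray  # (k, p) PCA loadings
    comp_mean: np.ndarray
    comp_std: np.ndarray

    @property
    def k(self) -> int:
        return self.components.shape[0]

    def transform(self, X: pd.DataFrame, strict: bool = True) -> np.ndarray:
        present = [c for c in self.feature_names if c in X.columns]
        if strict and len(present) < 0.5 * len(self.feature_names):
            raise ValueError(
                f"only {len(present)}/{len(self.feature_names)} model "
                "features present; refusing to predict"
            )
        if len(present) < len(self.feature_names):
            import warnings

            warnings.warn(
                f"{len(self.feature_names) - len(present)} model features "
                "missing; imputing 0 (word never used)"
            )
        mat = X.reindex(columns=self.feature_names, fill_value=0.0).to_numpy(
            dtype=float
        )
        z = (mat - self.mean) / self.std
        comps = z @ self.components.T
        return (comps - self.comp_mean) / self.comp_std


def fit_family_pca(
    X_selected: pd.DataFrame, config: SelectionConfig
) -> FamilyTransform:
    """Standardize selected columns and fit PCA capped at
    floor(pca_fraction·N_train) components (also bounded by matrix rank)."""
    mat = X_selected.to_numpy(dtype=float)
    n, p = mat.shape
    mean = mat.mean(axis=0)
    std = mat.std(axis=0, ddof=0)
    std = np.where(std > 0, std, 1.0)
    z = (mat - mean) / std
    k_cap = int(np.floor(config.pca_fraction * n))
    if k_cap < 1:
        raise ValueError(
            f"pca_fraction {config.pca_fraction} of {n} rows gives no "
            "component"
        )
    # deterministic full SVD; rank bound from nonzero singular values
    U, S, Vt = np.linalg.svd(z, full_matrices=False)
    tol = S.max() * max(n, p) * np.finfo(float).eps if S.size else 0.0
    rank = int((S > tol).sum())
    k = max(1, min(k_cap, rank, p))
    components = Vt[:k]
    comps = z @ components.T
    comp_mean = comps.mean(axis=0)
    comp_std = comps.std(axis=0, ddof=0)
    comp_std = np.where(comp_std > 0, comp_std, 1.0)
    return FamilyTransform(
        feature_names=list(X_selected.columns),
        mean=mean,
        std=std,
        components=components,
        comp_mean=comp_mean,
        comp_std=comp_std,
    )


@dataclass
class TraitModel:
    """A fitted language-based trait assessment."""

    families: dict[str, FamilyTransform]
    coef: np.ndarray
    intercept: float
    alpha: float
    config: SelectionConfig

    def family_order(self) -> list[str]:
        return list(self.families)

    def to_json(self) -> str:
        payload = {
            "schema_version": SCHEMA_VERSION,
            "alpha": self.alpha,
            "intercept": self.intercept,
            "coef": self.coef.tolist(),
            "config": {
                "univariate_p_threshold": self.config.univariate_p_threshold,
                "pca_fraction": self.config.pca_fraction,
                "ridge_alpha_grid": list(self.config.ridge_alpha_grid),
                "cv_folds": self.config.cv_folds,
                "seed": self.config.seed,
            },
            "families": {
                name: {
                    "feature_names": tr.feature_names,
                    "mean": tr.mean.tolist(),
                    "std": tr.std.tolist(),
                    "components": tr.components.tolist(),
                    "comp_mean": tr.comp_mean.tolist(),
                    "comp_std": tr.comp_std.tolist(),
                }
                for name, tr in self.families.items()
            },
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TraitModel":
        payload = json.loads(text)
        if payload.get("schema_version") != SCHEMA_VERSION:
            raise ValueError("unsupported model schema version")
        cfg = SelectionConfig(
            univariate_p_threshold=payload["config"]["univariate_p_threshold"],
            pca_fraction=payload["config"]["pca_fraction"],
            ridge_alpha_grid=tuple(payload["config"]["ridge_alpha_grid"]),
            cv_folds=payload["config"]["cv_folds"],
            seed=payload["config"]["seed"],
        )
        families = {
            name: FamilyTransform(
                feature_names=fam["feature_names"],
                mean=np.array(fam["mean"]),
                std=np.array(fam["std"]),
                components=np.array(fam["components"]),
                comp_mean=np.array(fam["comp_mean"]),
                comp_std=np.array(fam["comp_std"]),
            )
            for name, fam in payload["families"].items()
        }
        return cls(
            families=families,
            coef=np.array(payload["coef"]),
            intercept=float(payload["intercept"]),
            alpha=float(payload["alpha"]),
            config=cfg,
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "TraitModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_json(fh.read())


def _design_matrix(
    model_families: Mapping[str, FamilyTransform],
    families: Mapping[str, FeatureMatrix],
    strict: bool = True,
) -> np.ndarray:
    blocks = []
    for name, tr in model_families.items():
        if name not in families:
            raise KeyError(f"feature family {name!r} missing at predict time")
        blocks.append(tr.transform(families[name].values, strict=strict))
    return np.hstack(blocks)


def fit_trait_model(
    families: Mapping[str, FeatureMatrix],
    y: pd.Series,
    config: SelectionConfig | None = None,
    fixed_alpha: float | None = None,
) -> TraitModel:
    """Fit the full assessment on training rows.

    Selection, standardization and PCA are computed family by family on the
    training rows only; the concatenated components go to ridge regression.
    ``fixed_alpha`` skips the cross-validated penalty search (used for
    equivalence checks; normally the seeded CV chooses the penalty).
    """
    config = config or SelectionConfig()
    first = next(iter(families.values()))
    index = first.values.index
    n = len(index)
    if fixed_alpha is None and n < config.cv_folds:
        raise ValueError("fewer training rows than cv_folds")
    yv = y.loc[index]

    transforms: dict[str, FamilyTransform] = {}
    for name, fm in families.items():
        if not fm.values.index.equals(index):
            raise ValueError(f"family {name!r} rows are not aligned")
        selected = select_features(fm, yv, config)
        transforms[name] = fit_family_pca(fm.values[selected], config)

    Z = _design_matrix(transforms, families)
    yarr = yv.to_numpy(dtype=float)

    if fixed_alpha is not None:
        best_alpha = float(fixed_alpha)
    else:
        kf = KFold(n_splits=config.cv_folds, shuffle=True,
                   random_state=config.seed)
        best_alpha, best_mse = None, np.inf
        for a in config.ridge_alpha_grid:
            mse = 0.0
            for tr_idx, te_idx in kf.split(Z):
                ridge = Ridge(alpha=a)
                ridge.fit(Z[tr_idx], yarr[tr_idx])
                resid = yarr[te_idx] - ridge.predict(Z[te_idx])
                mse += float(resid @ resid)
            mse /= n
            if mse < best_mse:
                best_mse, best_alpha = mse, float(a)

    final = Ridge(alpha=best_alpha)
    final.fit(Z, yarr)
    return TraitModel(
        families=transforms,
        coef=np.asarray(final.coef_, dtype=float),
        intercept=float(final.intercept_),
        alpha=best_alpha,
        config=config,
    )


def predict_trait(
    model: TraitModel,
    families: Mapping[str, FeatureMatrix],
    strict: bool = True,
) -> pd.Series:
    """Deterministic linear scoring of new rows through the stored
    standardization, PCA loadings and ridge weights.

    Missing feature columns are imputed as 0 (the word was never used); by
    default prediction refuses to run when fewer than half of a family's
    features are resolvable.
    """
    Z = _design_matrix(model.families, families, strict=strict)
    scores = Z @ model.coef + model.intercept
    index = next(iter(families.values())).values.index
    return pd.Series(scores, index=index, name="trait_score")


@dataclass
class EvalReport:
    mse: float
    r: float
    r_disattenuated: float
    n_test: int


def evaluate(
    pred: pd.Series,
    y: pd.Series,
    rel_pred: float = 1.0,
    rel_y: float = 1.0,
) -> EvalReport:
    """MSE, Pearson r, and the disattenuated r of predictions vs. criterion."""
    common = pred.index.intersection(y.index)
    if len(common) < 3:
        raise ValueError("need at least 3 aligned observations")
    p = pred.loc[common].to_numpy(dtype=float)
    t = y.loc[common].to_numpy(dtype=float)
    if p.std(ddof=0) == 0 or t.std(ddof=0) == 0:
        raise ValueError("zero variance; correlation undefined")
    mse = float(np.mean((p - t) ** 2))
    r = float(np.corrcoef(p, t)[0, 1])
    return EvalReport(
        mse=mse,
        r=r,
        r_disattenuated=disattenuate(r, rel_pred, rel_y),
        n_test=len(common),
    )


def test_retest(
    model: TraitModel,
    corpus: MessageCorpus,
    bins: Sequence[tuple[datetime, datetime]],
    pipeline: FeaturePipeline,
    min_posts_per_bin: int = 1,
) -> pd.DataFrame:
    """Cross-time correlation matrix of model scores.

    Messages are partitioned into half-open time bins; users with at least
    ``min_posts_per_bin`` messages in every bin are scored separately per
    bin, and all pairwise product-moment correlations of the per-bin scores
    are reported (upper triangle filled, diagonal 1).
    """
    sub_corpora = [corpus.subset_time(start, end) for start, end in bins]
    qualifying: set[str] | None = None
    for sub in sub_corpora:
        counts = {uid: len(sub.messages_for(uid)) for uid in sub.user_ids}
        users = {uid for uid, c in counts.items() if c >= min_posts_per_bin}
        qualifying = users if qualifying is None else qualifying & users
    if not qualifying:
        raise ValueError("no user has enough posts in every time bin")
    preds = {}
    for i, sub in enumerate(sub_corpora):
        sub = sub.subset_users(qualifying)
        fams = pipeline.transform(sub)
        preds[f"time_{i + 1}"] = predict_trait(model, fams, strict=False)
    table = pd.DataFrame(preds)
    return table.corr(method="pearson")
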