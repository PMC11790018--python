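"""Random-forest biomarker nomination from multi-omics features.

Feature blocks (expression, methylation, mutation, CNV, clinical) are
column-bound after per-modality variable selection, prefiltered to the
top-k features by absolute Pearson correlation with the drug-response
measure, and fed to a seeded cross-validated random forest. Feature
importances (permutation importance on held-out folds by default) are
normalized by dividing by the maximum importance; features whose normalized
score reaches the threshold (default 0.3) are flagged as top biomarkers.
The slope of the least-squares line through the ranked importance profile,
divided by the maximum importance times the number of features, is reported
as a model-level concentration diagnostic: higher values mean importance is
concentrated on few features.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import accuracy_score, r2_score
from sklearn.model_selection import KFold

from .stats import bh_adjust, pearson_with_p

logger = logging.getLogger(__name__)

VARIABLE_K = 8000
PREFILTER_K = 400
TOP_SCORE_THRESHOLD = 0.3

CONTINUOUS_MODALITIES = ("expression", "methylation")


@dataclass
class FeatureTable:
    """Cell line x feature matrix with per-feature modality metadata."""

    values: pd.DataFrame  # samples x features
    modality: pd.Series  # feature -> modality

    def subset(self, features) -> "FeatureTable":
        return FeatureTable(
            values=self.values[features], modality=self.modality.loc[features]
        )


def select_variable_features(matrix: pd.DataFrame, k: int) -> pd.DataFrame:
    """Keep the k rows (features) of largest variance across samples.

    Ties break by feature id; ``k`` larger than the feature count keeps all
    rows with a logged warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= len(matrix):
        if k > len(matrix):
            logger.warning(
                "requested %d variable features but only %d available; keeping all",
                k,
                len(matrix),
            )
        return matrix.copy()
    variances = matrix.var(axis=1, ddof=0)
    order = sorted(matrix.index, key=lambda f: (-variances[f], f))
    keep = sorted(order[:k], key=lambda f: matrix.index.get_loc(f))
    return matrix.loc[keep]


def _standardize(block: pd.DataFrame) -> pd.DataFrame:
    mean = block.mean(axis=0)
    sd = block.std(axis=0, ddof=0).replace(0.0, 1.0)
    return (block - mean) / sd


def assemble_feature_table(
    expression: pd.DataFrame,
    methylation: pd.DataFrame,
    mutations: pd.DataFrame,
    cnv: pd.DataFrame,
    clinical: pd.DataFrame,
    variable_k: int = VARIABLE_K,
) -> FeatureTable:
    """Column-bind modality blocks into a cell line x feature table.

    Omics blocks arrive feature x sample; clinical arrives sample x column.
    Continuous blocks are reduced to the top ``variable_k`` variable
    features and z-scored; binary blocks pass through; clinical categorical
    columns are one-hot encoded. Samples absent from any block are dropped
    with a warning listing them; disjoint sample sets are an error.
    """
    omics = {
        "expression": expression,
        "methylation": methylation,
        "mutation": mutations,
        "cnv": cnv,
    }
    sample_sets = [set(m.columns) for m in omics.values()] + [set(clinical.index)]
    shared = set.intersection(*sample_sets)
    union = set.union(*sample_sets)
    if not shared:
        raise ValueError("feature blocks share no samples")
    dropped = sorted(union - shared)
    if dropped:
        logger.warning("dropping samples missing from some blocks: %s", dropped)
    samples = pd.Index(sorted(shared), name="sample_id")

    blocks: list[pd.DataFrame] = []
    modalities: list[pd.Series] = []
    for name, matrix in omics.items():
        sub = matrix[samples]
        if name in CONTINUOUS_MODALITIES:
            sub = select_variable_features(sub, variable_k)
            block = _standardize(sub.T)
        else:
            block = sub.T.astype(float)
        block.columns = [f"{name}:{f}" for f in block.columns]
        blocks.append(block)
        modalities.append(pd.Series(name, index=block.columns))

    clin = pd.get_dummies(clinical.loc[samples].astype(str), prefix_sep="=").astype(float)
    clin.columns = [f"clinical:{c}" for c in clin.columns]
    blocks.append(clin)
    modalities.append(pd.Series("clinical", index=clin.columns))

    values = pd.concat(blocks, axis=1)
    modality = pd.concat(modalities)
    modality.index.name = "feature"
    return FeatureTable(values=values, modality=modality)


def prefilter_top_correlated(
    features: FeatureTable, response: pd.Series, k: int = PREFILTER_K
) -> FeatureTable:
    """Keep the k features most correlated (|Pearson r|) with the response.

    Binary features use the same formula (point-biserial); zero-variance
    features get r = 0. Ties break by feature id.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    response = response.reindex(features.values.index)
    if response.isna().any():
        missing = response.index[response.isna()][0]
        raise ValueError(f"response missing for sample {missing!r}")
    y = response.to_numpy(dtype=float)
    X = features.values.to_numpy(dtype=float)
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, xc.T @ yc / np.where(denom > 0, denom, 1.0), 0.0)
    abs_r = pd.Series(np.abs(r), index=features.values.columns)
    if k >= len(abs_r):
        return features.subset(features.values.columns)
    order = sorted(abs_r.index, key=lambda f: (-abs_r[f], f))
    keep = [f for f in features.values.columns if f in set(order[:k])]
    return features.subset(keep)


def permutation_importances(model, X, y, n_repeats: int, rng: np.random.Generator):
    """Held-out permutation importance, evaluated in one batched prediction.

    For each feature, each repeat shuffles that column of ``X`` and records
    the drop in the model score (R^2 for regressors, accuracy for
    classifiers) relative to the unpermuted baseline. All permuted copies
    are stacked into a single ``predict`` call, which is algebraically
    identical to scoring them one at a time but traverses the forest once.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    is_regression = np.issubdtype(y.dtype, np.number)

    def score(pred, truth):
        if is_regression:
            return r2_score(truth, pred)
        return accuracy_score(truth, pred)

    baseline = score(model.predict(X), y)
    stacked = np.tile(X, (p * n_repeats, 1)).reshape(p, n_repeats, n, X.shape[1])
    for f in range(p):
        for r in range(n_repeats):
            stacked[f, r, :, f] = X[rng.permutation(n), f]
    preds = model.predict(stacked.reshape(p * n_repeats * n, X.shape[1]))
    preds = preds.reshape(p, n_repeats, n)
    drops = np.empty(p)
    for f in range(p):
        drops[f] = baseline - np.mean([score(preds[f, r], y) for r in range(n_repeats)])
    return drops


class RandomForestBiomarker(BaseEstimator):
    """Seeded, cross-validated random forest for drug-response prediction.

    Regression on the continuous response (AUC) is the primary mode; a
    classification mode on sensitive/resistant labels is available. Raw
    feature importances are permutation importances evaluated on each
    held-out fold and averaged (impurity importances selectable via
    ``importance_kind='impurity'``).

    Fitted attributes
    -----------------
    oof_predictions_ : pandas.Series
        Out-of-fold predictions, aligned to the training samples.
    feature_importances_ : pandas.Series
        Fold-averaged raw importances (negative permutation importances
        clipped at zero).
    performance_ : dict
        Out-of-fold Spearman correlation and R^2 (accuracy in
        classification mode).
    model_ : fitted forest on the full data, used by :meth:`predict`.
    """

    def __init__(
        self,
        n_trees: int = 300,
        cv_folds: int = 5,
        mode: str = "regression",
        importance_kind: str = "permutation",
        n_permutation_repeats: int = 3,
        max_features: str | float = "sqrt",
        random_state: int = 0,
    ):
        self.n_trees = n_trees
        self.cv_folds = cv_folds
        self.mode = mode
        self.importance_kind = importance_kind
        self.n_permutation_repeats = n_permutation_repeats
        self.max_features = max_features
        self.random_state = random_state

    def _make_forest(self):
        kwargs = dict(
            n_estimators=self.n_trees,
            max_features=self.max_features,
            random_state=self.random_state,
            n_jobs=1,
        )
        if self.mode == "regression":
            return RandomForestRegressor(**kwargs)
        if self.mode == "classification":
            return RandomForestClassifier(**kwargs)
        raise ValueError(f"mode must be 'regression' or 'classification', got {self.mode!r}")

    def fit(self, X: pd.DataFrame, y: pd.Series):
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if len(X) < 2 * self.cv_folds:
            raise ValueError(
                f"need at least {2 * self.cv_folds} samples for {self.cv_folds}-fold CV"
            )
        if self.importance_kind not in ("permutation", "impurity"):
            raise ValueError(f"unknown importance_kind {self.importance_kind!r}")
        X = pd.DataFrame(X)
        y = pd.Series(y).reindex(X.index)
        if y.isna().any():
            raise ValueError("response missing for some samples")

        kf = KFold(n_splits=self.cv_folds, shuffle=True, random_state=self.random_state)
        rng = np.random.default_rng(self.random_state)
        oof = pd.Series(index=X.index, dtype=float if self.mode == "regression" else object)
        importances = np.zeros(X.shape[1])
        for train_idx, test_idx in kf.split(X):
            model = self._make_forest()
            model.fit(X.iloc[train_idx].to_numpy(), y.iloc[train_idx].to_numpy())
            oof.iloc[test_idx] = model.predict(X.iloc[test_idx].to_numpy())
            if self.importance_kind == "permutation":
                drops = permutation_importances(
                    model,
                    X.iloc[test_idx],
                    y.iloc[test_idx],
                    n_repeats=self.n_permutation_repeats,
                    rng=rng,
                )
                importances += np.maximum(drops, 0.0)
            else:
                importances += model.feature_importances_
        importances /= self.cv_folds

        self.oof_predictions_ = oof
        self.feature_importances_ = pd.Series(importances, index=X.columns, name="importance")
        if self.mode == "regression":
            rho = sps.spearmanr(y.to_numpy(), oof.to_numpy(dtype=float)).statistic
            self.performance_ = {
                "spearman": float(rho),
                "r2": float(r2_score(y, oof.astype(float))),
            }
        else:
            self.performance_ = {"accuracy": float(accuracy_score(y, oof))}
        self.model_ = self._make_forest().fit(X.to_numpy(), y.to_numpy())
        self.feature_names_in_ = np.asarray(X.columns)
        return self

    def predict(self, X):
        return self.model_.predict(np.asarray(X, dtype=float))


def fit_rf_predict(
    features: FeatureTable | pd.DataFrame,
    response: pd.Series,
    **rf_params,
) -> RandomForestBiomarker:
    """Convenience wrapper: fit :class:`RandomForestBiomarker` on a table."""
    values = features.values if isinstance(features, FeatureTable) else features
    return RandomForestBiomarker(**rf_params).fit(values, response)


@dataclass
class ImportanceReport:
    """Per-feature normalized importances plus model-level diagnostics."""

    table: pd.DataFrame  # feature-indexed: raw_importance, rank, normalized_score, top_flag
    model_gradient: float
    model_concentration: float
    threshold: float

    @property
    def top_features(self) -> list[str]:
        return list(self.table.index[self.table["top_flag"]])


def normalize_importance(
    raw_importances: pd.Series, threshold: float = TOP_SCORE_THRESHOLD
) -> ImportanceReport:
    """Rank and normalize raw importances; flag top biomarkers.

    Importances are sorted descending (rank 1 = largest), the least-squares
    line through (rank, importance) gives the model gradient, and each
    feature's normalized score is its importance divided by the maximum.
    ``model_concentration`` is |gradient| / (max importance x n features).
    """
    raw = pd.Series(raw_importances).astype(float).clip(lower=0.0)
    if len(raw) < 2:
        raise ValueError("need at least 2 features")
    if (raw == 0).all():
        raise ValueError("all importances are zero; model is uninformative")
    order = sorted(raw.index, key=lambda f: (-raw[f], f))
    raw = raw.loc[order]
    ranks = np.arange(1, len(raw) + 1)
    slope = float(np.polyfit(ranks, raw.to_numpy(), 1)[0])
    max_imp = float(raw.iloc[0])
    normalized = raw / max_imp
    table = pd.DataFrame(
        {
            "raw_importance": raw,
            "rank": ranks,
            "normalized_score": normalized,
            "top_flag": normalized >= threshold,
        }
    )
    table.index.name = "feature"
    return ImportanceReport(
        table=table,
        model_gradient=abs(slope),
        model_concentration=abs(slope) / (max_imp * len(raw)),
        threshold=threshold,
    )


def single_correlate(
    features: FeatureTable | pd.DataFrame, response: pd.Series
) -> pd.DataFrame:
    """Per-feature Pearson correlation against the response, BH-adjusted.

    Rows are ranked by |r| descending (rank 1 = strongest association);
    zero-variance features get r = 0, p = 1 and are flagged.
    """
    values = features.values if isinstance(features, FeatureTable) else features
    response = response.reindex(values.index)
    if response.isna().any():
        raise ValueError("response missing for some samples")
    if len(values) < 4:
        raise ValueError("need at least 4 samples")
    y = response.to_numpy(dtype=float)
    rows = []
    for feature in values.columns:
        r, p, defined = pearson_with_p(values[feature].to_numpy(dtype=float), y)
        rows.append((feature, r, p, not defined))
    df = pd.DataFrame(rows, columns=["feature", "pearson_r", "p_value", "zero_variance"])
    df["bh_fdr"] = bh_adjust(df["p_value"].to_numpy())
    order = sorted(
        df.index, key=lambda i: (-abs(df.loc[i, "pearson_r"]), df.loc[i, "feature"])
    )
    rank = pd.Series(0, index=df.index)
    rank.loc[order] = np.arange(1, len(df) + 1)
    df["rank"] = rank
    return df.set_index("feature")
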