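"""SVM classifiers: the nested voting ensemble and the tuned single SVM.

The nested ensemble takes an ordered feature ranking of length N and
trains N polynomial-kernel SVMs: model i uses the top-i features.  At
prediction time each model casts one unweighted vote and the class
probability is the fraction of votes, so a sample's probability is exactly
the mean of the per-model hard calls.  An exact 0.5 tie is resolved by the
decision value of the model that sees all N features.

The single tuned SVM (used for the human plasma assay) selects its
hyperparameters by stratified k-fold cross-validation maximizing ROC AUC
over a small grid, then refits on all training data.  A clinical covariate
(APOE4 allele count) can be fused into any feature table as one extra
numeric column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, GridSearchCV
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureTable

logger = logging.getLogger("indicell")

#: Polynomial-kernel defaults: degree-3 inhomogeneous kernel, unit cost.
DEFAULT_KERNEL_PARAMS = {"degree": 3, "C": 1.0, "coef0": 1.0, "gamma": "scale"}

#: Hyperparameter grid searched by :func:`train_tuned_svm`.
DEFAULT_TUNING_GRID = {
    "C": [0.1, 1.0, 10.0],
    "degree": [2, 3],
    "gamma": [0.01, 0.1, 1.0],
}


def _encode_labels(labels: Sequence, positive_class: str) -> np.ndarray:
    y = np.asarray(labels)
    return (y == positive_class).astype(int)


@dataclass
class EnsembleModel:
    """N nested polynomial-kernel SVMs over an ordered feature list."""

    feature_ids: tuple
    models: list
    scaler: StandardScaler
    kernel_params: dict
    positive_class: str
    negative_class: str

    @property
    def n_models(self) -> int:
        return len(self.models)


@dataclass
class PredictionResult:
    """Votes, vote-fraction probabilities and hard labels per sample."""

    votes: pd.Series  # integer disease votes in 0..N
    probability: pd.Series  # votes / N
    label: pd.Series
    decision_values: pd.DataFrame  # sample x model
    n_models: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "votes": self.votes,
            "probability": self.probability,
            "label": self.label,
        })


def train_ensemble(
    features: FeatureTable,
    labels: Sequence,
    ranked_ids: Sequence[str],
    kernel_params: Mapping | None = None,
    seed: int = 0,
    positive_class: str = "carrier",
    negative_class: str = "non-carrier",
) -> EnsembleModel:
    """Fit the nested ensemble: model i uses the top-i ranked features.

    Features are standardized to zero mean / unit variance using training
    data only; the same standardization is applied at prediction time.
    """
    ranked_ids = list(ranked_ids)
    if not ranked_ids:
        raise ValueError("ranked_ids must be nonempty")
    y = _encode_labels(labels, positive_class)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in training labels")
    params = dict(DEFAULT_KERNEL_PARAMS)
    params.update(kernel_params or {})

    x_all = features.values[ranked_ids].to_numpy()
    scaler = StandardScaler().fit(x_all)
    x_all = scaler.transform(x_all)

    models = []
    for i in range(1, len(ranked_ids) + 1):
        svm = SVC(kernel="poly", random_state=seed, **params)
        try:
            svm.fit(x_all[:, :i], y)
        except Exception as exc:  # pragma: no cover - sklearn rarely fails here
            raise RuntimeError(
                f"SVM on top-{i} features {ranked_ids[:i]} failed to fit: {exc}"
            ) from exc
        models.append(svm)
    return EnsembleModel(
        feature_ids=tuple(ranked_ids),
        models=models,
        scaler=scaler,
        kernel_params=params,
        positive_class=positive_class,
        negative_class=negative_class,
    )


def predict_ensemble(model: EnsembleModel, features: FeatureTable) -> PredictionResult:
    """Count votes over the N nested models.

    probability = votes / N; label = disease iff probability > 0.5, with an
    exact 0.5 tie resolved by the sign of the full-feature model's decision
    value (it sees the most information).
    """
    missing = [f for f in model.feature_ids if f not in features.feature_ids]
    if missing:
        raise ValueError(f"features missing from table: {missing}")
    x = model.scaler.transform(features.values[list(model.feature_ids)].to_numpy())
    samples = features.sample_ids
    n = model.n_models

    votes = np.zeros(len(samples), dtype=int)
    decisions = np.zeros((len(samples), n))
    for i, svm in enumerate(model.models, start=1):
        d = svm.decision_function(x[:, :i])
        decisions[:, i - 1] = d
        votes += (svm.predict(x[:, :i]) == 1).astype(int)

    prob = votes / n
    full_d = decisions[:, -1]
    label = np.where(
        prob > 0.5, model.positive_class,
        np.where(prob < 0.5, model.negative_class,
                 np.where(full_d > 0, model.positive_class, model.negative_class)),
    )
    return PredictionResult(
        votes=pd.Series(votes, index=samples),
        probability=pd.Series(prob, index=samples),
        label=pd.Series(label, index=samples),
        decision_values=pd.DataFrame(
            decisions, index=samples, columns=[f"m{i}" for i in range(1, n + 1)]
        ),
        n_models=n,
    )


@dataclass
class TunedSvmModel:
    """Single polynomial-kernel SVM with CV-chosen hyperparameters."""

    feature_ids: tuple
    model: SVC
    scaler: StandardScaler
    best_params: dict
    cv_auc: float
    positive_class: str
    negative_class: str

    def decision_function(self, features: FeatureTable) -> pd.Series:
        x = self.scaler.transform(features.values[list(self.feature_ids)].to_numpy())
        return pd.Series(self.model.decision_function(x), index=features.sample_ids)

    def predict(self, features: FeatureTable) -> pd.Series:
        d = self.decision_function(features)
        return pd.Series(
            np.where(d > 0, self.positive_class, self.negative_class), index=d.index
        )


def train_tuned_svm(
    features: FeatureTable,
    labels: Sequence,
    fold_count: int = 10,
    seed: int = 0,
    grid: Mapping | None = None,
    positive_class: str = "carrier",
    negative_class: str = "non-carrier",
) -> TunedSvmModel:
    """Polynomial SVM tuned by stratified k-fold CV maximizing ROC AUC.

    The grid defaults to :data:`DEFAULT_TUNING_GRID`; the winning
    configuration is refit on all training data.  The fold count is capped
    at the smaller class size so every fold sees both classes.
    """
    y = _encode_labels(labels, positive_class)
    if len(features.sample_ids) < fold_count:
        raise ValueError("fewer samples than folds")
    class_sizes = np.bincount(y, minlength=2)
    if class_sizes.min() < 2:
        raise ValueError("both classes need >= 2 samples for stratified CV")
    k = int(min(fold_count, class_sizes.min()))
    if k < fold_count:
        logger.warning("fold count reduced from %d to %d to keep folds stratified",
                       fold_count, k)

    x = features.values.to_numpy()
    scaler = StandardScaler().fit(x)
    xs = scaler.transform(x)
    grid = dict(grid or DEFAULT_TUNING_GRID)
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    search = GridSearchCV(
        SVC(kernel="poly", coef0=1.0, random_state=seed),
        param_grid=grid,
        scoring="roc_auc",
        cv=cv,
        n_jobs=1,
    )
    search.fit(xs, y)
    return TunedSvmModel(
        feature_ids=tuple(features.feature_ids),
        model=search.best_estimator_,
        scaler=scaler,
        best_params=dict(search.best_params_),
        cv_auc=float(search.best_score_),
        positive_class=positive_class,
        negative_class=negative_class,
    )


def fuse_covariate(
    features: FeatureTable | None,
    meta: pd.DataFrame,
    covariate: str = "apoe4_count",
) -> FeatureTable:
    """Append a clinical covariate as one numeric feature.

    With ``features=None`` a covariate-only single-feature table is
    returned.  Missing covariate values are an error naming the samples.
    """
    if features is not None:
        samples = features.sample_ids
    else:
        samples = meta.index
    values = pd.to_numeric(meta.loc[samples, covariate], errors="coerce")
    if values.isna().any():
        bad = list(values.index[values.isna()])
        raise ValueError(f"covariate {covariate!r} missing for samples: {bad}")
    cov_table = FeatureTable(
        values=values.to_frame(covariate),
        kinds=pd.Series("covariate", index=[covariate]),
        provenance={covariate: "sample metadata"},
    )
    if features is None:
        return cov_table
    return features.concat(cov_table)


def save_model(model, path) -> None:
    """Serialize a model with a format version tag."""
    joblib.dump({"format_version": 1, "model": model}, path)


def load_model(path):
    payload = joblib.load(path)
    if payload.get("format_version") != 1:
        raise ValueError(f"unsupported model archive version: {payload.get('format_version')}")
    return payload["model"]
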