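"""Minimum-entropy active learning for blinded test-set prediction.

The blinded evaluation protocol predicts one unlabeled sample at a time:
the sample whose predicted class distribution has the *lowest* entropy is
predicted first, its true label is then revealed by an oracle, the labeled
example joins the training set, and the classifier is retrained before the
next pick.  Predicting confident samples first lets the classifier absorb,
e.g., a batch shift between training and test data without ever seeing a
label before committing to that sample's prediction.

Class probabilities come from a single polynomial-kernel SVM whose
decision values are calibrated with a Laplacian distribution fitted on
3-fold cross-validated residuals (residual = +/-1 encoded label minus
decision value).  Entropy ties are broken with the entropy of the nested
ensemble's vote fraction, then by sample id.

Every loop iteration is logged to a transcript whose entries are hash
chained: each prediction is hashed (together with the previous entry's
hash) *before* the oracle reveals the label, so the transcript proves that
no prediction could have been altered after label disclosure.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .classify import (
    DEFAULT_KERNEL_PARAMS,
    EnsembleModel,
    PredictionResult,
    predict_ensemble,
    train_ensemble,
)
from .features import FeatureTable

logger = logging.getLogger("indicell")

SCALE_FLOOR = 1e-12


@dataclass
class ResidualModel:
    """Laplacian location/scale of cross-validated SVM residuals."""

    location: float
    scale: float

    def prob_positive(self, decision_value: float | np.ndarray) -> np.ndarray:
        """P(disease | decision value d) = 1 - F(-d), F the fitted CDF."""
        return 1.0 - stats.laplace.cdf(-np.asarray(decision_value, dtype=float),
                                       loc=self.location, scale=self.scale)


@dataclass
class CandidateScore:
    sample_id: str
    probability: float
    entropy: float  # bits
    ensemble_entropy: float  # tie-break, bits


def binary_entropy(p: float | np.ndarray) -> np.ndarray:
    """Entropy of a Bernoulli(p) in bits; 0 at p in {0, 1}."""
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -(p * np.log2(p)) - (q * np.log2(q))
    return np.where((p <= 0) | (p >= 1), 0.0, h)


def _fit_single_svm(features: FeatureTable, y: np.ndarray,
                    kernel_params: Mapping | None, seed: int):
    params = dict(DEFAULT_KERNEL_PARAMS)
    params.update(kernel_params or {})
    scaler = StandardScaler().fit(features.values.to_numpy())
    svm = SVC(kernel="poly", random_state=seed, **params)
    svm.fit(scaler.transform(features.values.to_numpy()), y)
    return svm, scaler


def fit_residual_laplace(
    features: FeatureTable,
    labels: Sequence,
    kernel_params: Mapping | None = None,
    seed: int = 0,
    positive_class: str = "carrier",
    method: str = "median_mad",
) -> ResidualModel:
    """Laplacian on 3-fold cross-validated decision-value residuals.

    Residual = (+1 for disease, -1 for control) minus the decision value of
    an SVM trained on the other two folds.  ``method="median_mad"`` uses
    location = median and scale = mean absolute deviation from it (the
    Laplace MLE given the location); ``"mle"`` fits both by maximum
    likelihood.  A zero scale is floored at machine tolerance.
    """
    y = (np.asarray(labels) == positive_class).astype(int)
    if len(y) < 6:
        raise ValueError("need at least 6 labeled samples for 3-fold residuals")
    encoded = np.where(y == 1, 1.0, -1.0)
    cv = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
    residuals = np.empty(len(y))
    x = features.values.to_numpy()
    for train_idx, test_idx in cv.split(x, y):
        sub = FeatureTable(
            features.values.iloc[train_idx], features.kinds, dict(features.provenance)
        )
        svm, scaler = _fit_single_svm(sub, y[train_idx], kernel_params, seed)
        d = svm.decision_function(scaler.transform(x[test_idx]))
        residuals[test_idx] = encoded[test_idx] - d

    if method == "mle":
        location, scale = stats.laplace.fit(residuals)
    else:
        location = float(np.median(residuals))
        scale = float(np.mean(np.abs(residuals - location)))
    if scale <= 0:
        logger.warning("residual scale is zero; flooring at %g", SCALE_FLOOR)
        scale = SCALE_FLOOR
    return ResidualModel(location=location, scale=scale)


def candidate_entropies(
    svm_model,
    scaler,
    residual_model: ResidualModel,
    unlabeled: FeatureTable,
    ensemble: EnsembleModel | None = None,
) -> list[CandidateScore]:
    """Score every unlabeled sample by predicted-class entropy (bits)."""
    d = svm_model.decision_function(scaler.transform(unlabeled.values.to_numpy()))
    p = residual_model.prob_positive(d)
    h = binary_entropy(p)
    if ensemble is not None:
        ens = predict_ensemble(ensemble, unlabeled)
        h_ens = binary_entropy(ens.probability.to_numpy())
    else:
        h_ens = np.ones_like(h)
    return [
        CandidateScore(
            sample_id=str(s), probability=float(pi),
            entropy=float(hi), ensemble_entropy=float(he),
        )
        for s, pi, hi, he in zip(unlabeled.sample_ids, p, h, h_ens)
    ]


def pick_candidate(scores: Sequence[CandidateScore]) -> CandidateScore:
    """Minimum entropy; ties broken by ensemble entropy, then sample id."""
    return min(scores, key=lambda c: (c.entropy, c.ensemble_entropy, c.sample_id))


@dataclass
class TranscriptEntry:
    iteration: int
    sample_id: str
    probability: float
    entropy: float
    predicted_label: str
    commit_hash: str
    revealed_label: str | None = None


def _commit(prev_hash: str, payload: dict) -> str:
    msg = prev_hash + json.dumps(payload, sort_keys=True)
    return hashlib.sha256(msg.encode()).hexdigest()


def verify_transcript(transcript: Sequence[TranscriptEntry]) -> bool:
    """Replay the hash chain; True iff no committed prediction was altered."""
    prev = ""
    for e in transcript:
        payload = {
            "iteration": e.iteration, "sample_id": e.sample_id,
            "probability": e.probability, "entropy": e.entropy,
            "predicted_label": e.predicted_label,
        }
        if _commit(prev, payload) != e.commit_hash:
            return False
        prev = e.commit_hash
    return True


def active_loop(
    train_features: FeatureTable,
    train_labels: Sequence,
    unlabeled: FeatureTable,
    oracle: Callable[[str], str | None] | Mapping[str, str],
    ranked_ids: Sequence[str] | None = None,
    kernel_params: Mapping | None = None,
    seed: int = 0,
    positive_class: str = "carrier",
    negative_class: str = "non-carrier",
) -> list[TranscriptEntry]:
    """Run the minimum-entropy loop until no unlabeled samples remain.

    Each iteration: fit the single SVM and its Laplacian calibration plus
    the nested ensemble on the current training set, score all remaining
    unlabeled samples, pick the minimum-entropy candidate, commit its
    prediction to the hash-chained transcript, then ask the oracle for the
    true label and fold the sample into the training set.  The features
    are fixed across iterations; only the SVMs are refit.  An oracle
    returning None halts the loop and the partial transcript is returned.
    """
    if ranked_ids is None:
        ranked_ids = list(train_features.feature_ids)
    if isinstance(oracle, Mapping):
        oracle_map = dict(oracle)
        oracle = oracle_map.get

    labels = list(train_labels)
    current = FeatureTable(
        train_features.values[list(ranked_ids)].copy(),
        train_features.kinds.loc[list(ranked_ids)],
        dict(train_features.provenance),
    )
    remaining = FeatureTable(
        unlabeled.values[list(ranked_ids)].copy(),
        unlabeled.kinds.loc[list(ranked_ids)],
        dict(unlabeled.provenance),
    )

    transcript: list[TranscriptEntry] = []
    prev_hash = ""
    iteration = 0
    while remaining.values.shape[0] > 0:
        iteration += 1
        y = np.array(labels)
        svm, scaler = _fit_single_svm(current, (y == positive_class).astype(int),
                                      kernel_params, seed)
        residual = fit_residual_laplace(current, labels, kernel_params, seed,
                                        positive_class)
        ensemble = train_ensemble(current, labels, ranked_ids, kernel_params,
                                  seed, positive_class, negative_class)
        scores = candidate_entropies(svm, scaler, residual, remaining, ensemble)
        chosen = pick_candidate(scores)

        ens_pred = predict_ensemble(
            ensemble,
            FeatureTable(remaining.values.loc[[chosen.sample_id]],
                         remaining.kinds, dict(remaining.provenance)),
        )
        predicted = str(ens_pred.label.iloc[0])
        payload = {
            "iteration": iteration, "sample_id": chosen.sample_id,
            "probability": chosen.probability, "entropy": chosen.entropy,
            "predicted_label": predicted,
        }
        commit = _commit(prev_hash, payload)
        entry = TranscriptEntry(commit_hash=commit, **payload)
        transcript.append(entry)
        prev_hash = commit

        revealed = oracle(chosen.sample_id)
        if revealed is None:
            logger.warning("oracle refused a label for %s; halting loop",
                           chosen.sample_id)
            return transcript
        entry.revealed_label = str(revealed)

        current = FeatureTable(
            pd.concat([current.values, remaining.values.loc[[chosen.sample_id]]]),
            current.kinds, dict(current.provenance),
        )
        labels.append(str(revealed))
        remaining = FeatureTable(
            remaining.values.drop(index=chosen.sample_id),
            remaining.kinds, dict(remaining.provenance),
        )
    return transcript


def transcript_to_frame(transcript: Sequence[TranscriptEntry]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "iteration": e.iteration, "sample_id": e.sample_id,
            "probability": e.probability, "entropy": e.entropy,
            "predicted_label": e.predicted_label,
            "revealed_label": e.revealed_label, "commit_hash": e.commit_hash,
        }
        for e in transcript
    ])
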