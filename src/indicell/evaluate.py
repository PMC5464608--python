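"""Performance statistics and cross-validation harnesses.

Conventions (each verified against worked examples and kept as defaults,
with the textbook alternative behind a flag):

* The binomial test on k correct of n calls uses the *strictly greater*
  tail P(X > k) under X ~ Binomial(n, 0.5).
* The MCC p-value treats the MCC as a Pearson correlation over n paired
  calls and applies the correlation t-test, t = MCC * sqrt((n-2)/(1-MCC^2))
  with n-2 degrees of freedom, two-sided.  A Fisher z-transform variant is
  available via ``method="fisher_z"``.
* Prediction FDR is FP/(TP+FP) — a property of a classifier's calls, not
  to be confused with Benjamini-Hochberg q-values across classifiers.
* The vote-threshold ROC sweeps the number of ensemble votes required for
  a disease call; its trapezoid AUC equals the tie-corrected pairwise
  comparison (Mann-Whitney) statistic.

Rates with zero denominators are reported as undefined (NaN), never as 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("indicell")


# ---------------------------------------------------------------------------
# confusion metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    fpr: float
    fdr: float  # prediction FDR = FP/(TP+FP)
    f1: float
    mcc: float
    binomial_p: float
    mcc_p: float
    auc: float = float("nan")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return {
            "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "FPR": self.fpr, "FDR": self.fdr,
            "F1": self.f1, "MCC": self.mcc, "binomial_p": self.binomial_p,
            "MCC_p": self.mcc_p, "AUC": self.auc,
        }


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def confusion_metrics(
    predicted: Sequence,
    actual: Sequence,
    positive_class: str = "carrier",
    votes: Sequence[int] | None = None,
    n_models: int | None = None,
) -> ConfusionMetrics:
    """All confusion-matrix statistics for binary disease calls.

    ``positive_class`` is the disease label; every other label counts as
    negative.  If per-sample ensemble ``votes`` are supplied the
    vote-threshold ROC AUC is included.
    """
    predicted = np.asarray(predicted)
    actual = np.asarray(actual)
    if predicted.shape != actual.shape:
        raise ValueError("predicted and actual must align")
    pred_pos = predicted == positive_class
    act_pos = actual == positive_class
    tp = int((pred_pos & act_pos).sum())
    fp = int((pred_pos & ~act_pos).sum())
    tn = int((~pred_pos & ~act_pos).sum())
    fn = int((~pred_pos & act_pos).sum())
    n = tp + fp + tn + fn

    accuracy = _ratio(tp + tn, n)
    sensitivity = _ratio(tp, tp + fn)
    specificity = _ratio(tn, tn + fp)
    fpr = _ratio(fp, tn + fp)
    fdr = _ratio(fp, tp + fp)
    f1 = _ratio(2 * tp, 2 * tp + fp + fn)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom > 0 else float("nan")

    binom_p = binomial_pvalue_strict(tp + tn, n)
    mcc_p = mcc_pvalue_t(mcc, n) if np.isfinite(mcc) and n >= 4 else float("nan")

    auc = float("nan")
    if votes is not None:
        if n_models is None:
            n_models = int(np.max(votes))
        auc, _ = roc_auc_votes(votes, actual, n_models, positive_class)

    return ConfusionMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn, accuracy=accuracy, sensitivity=sensitivity,
        specificity=specificity, fpr=fpr, fdr=fdr, f1=f1, mcc=float(mcc),
        binomial_p=binom_p, mcc_p=mcc_p, auc=auc,
    )


# ---------------------------------------------------------------------------
# p-value conventions
# ---------------------------------------------------------------------------

def binomial_pvalue_strict(
    k_correct: int, n: int, p0: float = 0.5, convention: str = "greater_strict"
) -> float:
    """Binomial tail probability of the observed number of correct calls.

    ``"greater_strict"`` (default): P(X > k), which is 0 at k = n — the
    degenerate edge of the strict convention.  ``"greater_equal"``: the
    textbook P(X >= k).
    """
    if not 0 <= k_correct <= n:
        raise ValueError("k_correct must be in [0, n]")
    if convention == "greater_strict":
        return float(stats.binom.sf(k_correct, n, p0))
    if convention == "greater_equal":
        return float(stats.binom.sf(k_correct - 1, n, p0))
    raise ValueError(f"unknown convention {convention!r}")


def mcc_pvalue_t(mcc: float, n: int, method: str = "t") -> float:
    """Two-sided significance of an MCC over n paired binary calls.

    ``"t"`` (default): correlation t-test with n-2 degrees of freedom.
    ``"fisher_z"``: Fisher z-transform against a normal null.
    |MCC| = 1 leaves no residual variance; the df-limit value 0 is
    returned with a warning flag in the log.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if abs(mcc) >= 1:
        logger.warning("|MCC| = 1: p-value reported at its df-limit (0)")
        return 0.0
    if method == "t":
        t = mcc * np.sqrt((n - 2) / (1.0 - mcc * mcc))
        return float(2.0 * stats.t.sf(abs(t), n - 2))
    if method == "fisher_z":
        z = np.arctanh(mcc) * np.sqrt(n - 3)
        return float(2.0 * stats.norm.sf(abs(z)))
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# vote-threshold ROC
# ---------------------------------------------------------------------------

def roc_auc_votes(
    votes: Sequence[int],
    actual: Sequence,
    n_models: int,
    positive_class: str = "carrier",
) -> tuple[float, pd.DataFrame]:
    """ROC by sweeping the number of votes required for a disease call.

    Returns (AUC, curve).  The trapezoid AUC over the swept thresholds
    equals the Mann-Whitney pairwise-comparison statistic with ties
    counted 0.5.  Undefined (NaN) if only one class is present.
    """
    votes = np.asarray(votes, dtype=float)
    actual = np.asarray(actual)
    if np.any((votes < 0) | (votes > n_models)):
        raise ValueError("votes must lie in 0..n_models")
    pos = actual == positive_class
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    curve_rows = []
    for thr in range(n_models + 1, -1, -1):  # strictest first
        call_pos = votes >= thr
        tpr = _ratio((call_pos & pos).sum(), n_pos)
        fpr = _ratio((call_pos & ~pos).sum(), n_neg)
        curve_rows.append({"threshold": thr, "fpr": fpr, "tpr": tpr})
    curve = pd.DataFrame(curve_rows)
    if n_pos == 0 or n_neg == 0:
        logger.warning("ROC undefined: only one class present")
        return float("nan"), curve
    auc = float(np.trapezoid(curve["tpr"], curve["fpr"]))
    return auc, curve


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values over the supplied tests."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrichment(hits: set, annotation: set, universe: int) -> float:
    """Upper-tail hypergeometric p of the observed overlap or larger."""
    if universe <= 0:
        raise ValueError("empty universe")
    hits, annotation = set(hits), set(annotation)
    if len(hits) > universe or len(annotation) > universe:
        raise ValueError("hits and annotation must fit inside the universe")
    overlap = len(hits & annotation)
    return float(stats.hypergeom.sf(overlap - 1, universe, len(annotation), len(hits)))


# ---------------------------------------------------------------------------
# cross-validation harnesses
# ---------------------------------------------------------------------------

@dataclass
class CvResult:
    """Predictions, pooled metrics and per-repetition metrics of a CV run."""

    predictions: pd.DataFrame  # sample_id, repetition, fold, predicted, actual
    pooled: ConfusionMetrics
    per_repetition: pd.DataFrame  # one metrics row per repetition
    selection_logs: list  # selected-feature list per training set


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator):
    """Stratified fold assignment; every fold holds both classes if possible."""
    folds = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        folds[idx] = np.arange(len(idx)) % k
    return folds


def cv_harness(
    fit_predict: Callable,
    sample_ids: Sequence[str],
    labels: Sequence[str],
    mode: str = "loocv",
    k: int = 16,
    n_reps: int = 100,
    seed: int = 0,
    positive_class: str = "carrier",
) -> CvResult:
    """Run LOOCV or repeated stratified k-fold around a training pipeline.

    ``fit_predict(train_ids, train_labels, test_ids)`` must perform *all*
    feature selection and tuning using only the training split (the
    leakage contract) and return ``(predicted_labels, selected_features)``
    for the test split.  Every sample is predicted exactly once per
    repetition; LOOCV is a single repetition of n folds.
    """
    sample_ids = list(sample_ids)
    labels = list(labels)
    y = np.asarray(labels)
    n = len(sample_ids)
    rng = np.random.default_rng(seed)

    if mode == "loocv":
        reps = [("loocv", np.arange(n))]  # fold index = sample index
    elif mode == "repeated_kfold":
        if min(np.bincount((y == positive_class).astype(int))) < k:
            # with fewer samples than folds in a class some folds would be
            # single-class; keep stratification and abort otherwise
            if min(np.bincount((y == positive_class).astype(int))) < 2:
                raise ValueError("a class has < 2 samples; cannot stratify")
        reps = [
            (rep, _stratified_folds(y, k, rng)) for rep in range(n_reps)
        ]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    rows = []
    selection_logs = []
    per_rep_metrics = []
    for rep, folds in reps:
        rep_pred = {}
        for fold in np.unique(folds):
            test_mask = folds == fold
            train_ids = [s for s, m in zip(sample_ids, test_mask) if not m]
            test_ids = [s for s, m in zip(sample_ids, test_mask) if m]
            train_labels = [l for l, m in zip(labels, test_mask) if not m]
            predicted, selected = fit_predict(train_ids, train_labels, test_ids)
            selection_logs.append(list(selected))
            for s, p in zip(test_ids, predicted):
                rep_pred[s] = p
                rows.append({
                    "sample_id": s, "repetition": rep, "fold": int(fold),
                    "predicted": p, "actual": labels[sample_ids.index(s)],
                })
        rep_predicted = [rep_pred[s] for s in sample_ids]
        m = confusion_metrics(rep_predicted, labels, positive_class)
        per_rep_metrics.append({"repetition": rep, **m.to_dict()})

    predictions = pd.DataFrame(rows)
    pooled = confusion_metrics(
        predictions["predicted"].to_numpy(), predictions["actual"].to_numpy(),
        positive_class,
    )
    return CvResult(
        predictions=predictions,
        pooled=pooled,
        per_repetition=pd.DataFrame(per_rep_metrics),
        selection_logs=selection_logs,
    )


def compare_cv(a: CvResult, b: CvResult, metric: str = "accuracy") -> float:
    """Two-sided Wilcoxon signed-rank p comparing per-repetition metrics."""
    x = a.per_repetition[metric].to_numpy()
    y = b.per_repetition[metric].to_numpy()
    if len(x) != len(y):
        raise ValueError("CV results must have the same number of repetitions")
    if np.allclose(x, y):
        return 1.0
    return float(stats.wilcoxon(x, y).pvalue)


def feature_stability(
    selection_logs: Sequence[Sequence[str]], threshold: float = 0.5
) -> list[str]:
    """Features selected in at least ``threshold`` of the training sets."""
    if not selection_logs:
        raise ValueError("need at least one selection log")
    counts: dict[str, int] = {}
    for log in selection_logs:
        for f in set(log):
            counts[f] = counts.get(f, 0) + 1
    n = len(selection_logs)
    return sorted(f for f, c in counts.items() if c / n >= threshold)
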