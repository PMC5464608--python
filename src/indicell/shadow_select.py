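"""Shadow-feature FWER ranking of candidate classifier features.

Every real feature is duplicated as a *shadow*: a copy whose values are
permuted across samples, destroying any association with the class label
while preserving the marginal distribution.  An importance engine (a
random forest by default, a simplified random-fern ensemble as an
experimental alternative) scores real and shadow features together, and a
feature's family-wise error rate is the fraction of repetitions in which
the best shadow matched or beat it:

    FWER(f) = #{reps : max importance over all shadows >= importance(f)} / n_reps

Features with FWER < 1.0 — i.e. those that beat every shadow at least
once — are retained and ranked by FWER (ascending), ties broken by mean
importance (descending).  The lenient cutoff deliberately discards only
features that are indistinguishable from noise in every repetition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .features import FeatureTable

logger = logging.getLogger("indicell")


@dataclass
class RankedFeature:
    feature_id: str
    fwer: float
    importance: float  # mean importance across repetitions
    rank: int  # 1 = best


def _forest_importances(
    x: np.ndarray, y: np.ndarray, n_trees: int, seed: int
) -> np.ndarray:
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    )
    forest.fit(x, y)
    return forest.feature_importances_


def _fern_importances(
    x: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    n_ferns: int = 300,
    depth: int = 2,
) -> np.ndarray:
    """Simplified random-fern importance (experimental).

    Each fern thresholds ``depth`` randomly drawn features at their medians
    and scores the resulting bin assignment by its mutual information with
    the class label; member features accumulate the fern score.
    """
    n_samples, n_feat = x.shape
    classes, y_idx = np.unique(y, return_inverse=True)
    binary = x > np.median(x, axis=0)
    importances = np.zeros(n_feat)
    counts_per_feat = np.zeros(n_feat)
    for _ in range(n_ferns):
        feats = rng.choice(n_feat, size=min(depth, n_feat), replace=False)
        bins = np.zeros(n_samples, dtype=int)
        for j, f in enumerate(feats):
            bins |= binary[:, f].astype(int) << j
        # mutual information between bin index and class, Laplace-smoothed
        joint = np.zeros((bins.max() + 1, len(classes)))
        np.add.at(joint, (bins, y_idx), 1.0)
        joint += 0.5
        joint /= joint.sum()
        pb = joint.sum(axis=1, keepdims=True)
        pc = joint.sum(axis=0, keepdims=True)
        mi = float((joint * np.log(joint / (pb @ pc))).sum())
        importances[feats] += mi
        counts_per_feat[feats] += 1
    counts_per_feat[counts_per_feat == 0] = 1
    return importances / counts_per_feat


def compute_fwer(
    features: FeatureTable | pd.DataFrame,
    labels: Sequence,
    backend: str = "forest",
    n_trees: int = 1000,
    n_reps: int = 100,
    seed: int = 0,
) -> list[RankedFeature]:
    """Shadow-based FWER and importance rank for every feature.

    ``labels`` must contain at least two classes and ``n_reps`` must be at
    least 20 so the FWER grid is not too coarse.  Constant (zero-variance)
    features cannot be scored meaningfully and are dropped with a warning.
    The result is column-order invariant: features are processed in sorted
    id order internally.
    """
    if isinstance(features, FeatureTable):
        values = features.values
    else:
        values = features
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain at least 2 classes")
    if n_reps < 20:
        raise ValueError("n_reps must be >= 20")

    values = values[sorted(values.columns)]
    sd = values.std(axis=0)
    dead = list(values.columns[(sd == 0) | ~np.isfinite(sd)])
    if dead:
        logger.warning("dropping %d constant features before shadow ranking: %s",
                       len(dead), dead[:5])
        values = values.drop(columns=dead)
    if values.shape[1] == 0:
        raise ValueError("no non-constant features to rank")

    x = values.to_numpy()
    n_samples, n_feat = x.shape
    beaten = np.zeros(n_feat)
    imp_sum = np.zeros(n_feat)
    root = np.random.SeedSequence(seed)
    for rep, child in enumerate(root.spawn(n_reps)):
        rng = np.random.default_rng(child)
        shadow = np.column_stack([rng.permutation(x[:, j]) for j in range(n_feat)])
        both = np.hstack([x, shadow])
        if backend == "forest":
            rep_seed = int(rng.integers(0, 2**31 - 1))
            imp = _forest_importances(both, y, n_trees, rep_seed)
        elif backend == "ferns":
            imp = _fern_importances(both, y, rng)
        else:
            raise ValueError(f"unknown backend {backend!r}")
        real, sh = imp[:n_feat], imp[n_feat:]
        beaten += sh.max() >= real
        imp_sum += real

    fwer = beaten / n_reps
    mean_imp = imp_sum / n_reps
    order = np.lexsort((-mean_imp, fwer))  # fwer asc, importance desc
    ranked = [
        RankedFeature(
            feature_id=str(values.columns[j]),
            fwer=float(fwer[j]),
            importance=float(mean_imp[j]),
            rank=r + 1,
        )
        for r, j in enumerate(order)
    ]
    return ranked


def rank_for_ensemble(
    ranked: Sequence[RankedFeature], cutoff: float = 1.0
) -> list[str]:
    """Ordered ids of features passing the FWER cutoff (< cutoff).

    The length of the result is the size N of the nested ensemble built on
    top of it.
    """
    if not ranked:
        raise ValueError("empty ranked feature list")
    kept = [f.feature_id for f in sorted(ranked, key=lambda f: f.rank)
            if f.fwer < cutoff]
    if not kept:
        raise ValueError(
            "no features pass the FWER cutoff; consider more repetitions "
            "or stronger candidate features"
        )
    return kept


def ranked_to_frame(ranked: Sequence[RankedFeature]) -> pd.DataFrame:
    """Serializable table (id, fwer, importance, rank)."""
    return pd.DataFrame(
        [(f.feature_id, f.fwer, f.importance, f.rank) for f in ranked],
        columns=["feature_id", "fwer", "importance", "rank"],
    ).set_index("feature_id")
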