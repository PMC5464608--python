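"""End-to-end classifier pipeline and the 16-configuration grid.

A single :class:`DiseaseClassifierPipeline` chains the stages in the order
the assay analysis runs them: marker-model normalization (fit on training
non-carriers only) -> per-gene Welch statistics -> gene-set maxmean scores
with permutation restandardization -> set- or gene-level features ->
shadow-FWER ranking -> nested SVM voting ensemble.  Prediction is either
static (one shot) or via the minimum-entropy active-learning loop.

Everything that touches disease labels happens inside ``fit``, so wrapping
``fit``/``predict`` in a cross-validation harness keeps feature selection
inside each training fold.

The four boolean-ish design choices — gene-set score regime (down-only vs
two-sided), feature kind (set vs gene), shadow selection on/off, active
learning on/off — span a 2^4 grid of classifier configurations;
:func:`run_grid` trains all 16 and tallies how often an off-signature
cohort is called non-carrier.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field, asdict, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import active_learn, classify, evaluate, features as feat, preprocess, shadow_select
from .features import FeatureTable, GeneSetCollection
from .preprocess import DEFAULT_MARKER_GENES, ExonMatrix, ExpressionMatrix

logger = logging.getLogger("indicell")


@dataclass(frozen=True)
class RunConfig:
    """Mode flags and sizes for one classifier configuration.

    The four mode fields (gsa_regime, feature_kind, use_shadow_selection,
    use_active_learning) span the full 2^4 configuration grid.
    """

    gsa_regime: str = "down_only"  # down_only | two_sided
    feature_kind: str = "gene_set"  # gene_set | gene
    use_shadow_selection: bool = True
    use_active_learning: bool = False
    n_trees: int = 1000  # forest size for shadow ranking (10000 = robustness variant)
    n_perm: int = 1000  # label permutations for set-score restandardization
    shadow_reps: int = 100
    shadow_backend: str = "forest"
    gsa_threshold: float = 1.0
    gene_alpha: float = 0.05  # individual differential filter for gene features
    marker_genes: tuple = DEFAULT_MARKER_GENES
    qc_alpha: float = 0.05
    svm_degree: int = 3
    svm_cost: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.gsa_regime not in ("down_only", "two_sided"):
            raise ValueError(f"unknown gsa_regime {self.gsa_regime!r}")
        if self.feature_kind not in ("gene_set", "gene"):
            raise ValueError(f"unknown feature_kind {self.feature_kind!r}")
        if self.n_trees < 1 or self.n_perm < 1 or self.shadow_reps < 20:
            raise ValueError("n_trees/n_perm must be >= 1 and shadow_reps >= 20")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @property
    def kernel_params(self) -> dict:
        return {"degree": self.svm_degree, "C": self.svm_cost}


def sixteen_grid(base: RunConfig) -> list[RunConfig]:
    """All 2^4 combinations of the four mode flags, other fields from base."""
    grid = []
    for regime, kind, shadow, active in itertools.product(
        ("down_only", "two_sided"), ("gene_set", "gene"), (True, False), (True, False)
    ):
        grid.append(replace(base, gsa_regime=regime, feature_kind=kind,
                            use_shadow_selection=shadow, use_active_learning=active))
    return grid


class DiseaseClassifierPipeline:
    """Trainable serum-response disease classifier (one configuration)."""

    def __init__(self, config: RunConfig):
        config.validate()
        self.config = config
        self.marker_model = None
        self.diff = None
        self.selected_sets: list | None = None
        self.selected_genes: list | None = None
        self.ranked_ids: list | None = None
        self.ensemble = None
        self._train_features: FeatureTable | None = None
        self._train_labels: list | None = None

    # -- internals ---------------------------------------------------------

    def _to_ratios(self, matrix, meta=None) -> ExpressionMatrix:
        m = preprocess.summarize_exons(matrix)
        if m.scale == preprocess.LOG2_RATIO:
            return m
        if self.marker_model is None:
            raise RuntimeError("marker model not fitted")
        return preprocess.normalize_log2ratio(m, model=self.marker_model)

    def _build_features(self, ratios: ExpressionMatrix, sets: GeneSetCollection) -> FeatureTable:
        if self.config.feature_kind == "gene_set":
            return feat.aggregate_set_features(ratios, sets.subset(self.selected_sets))
        return feat.gene_features(ratios, self.selected_genes)

    # -- fitting -----------------------------------------------------------

    def fit(self, matrix, meta: pd.DataFrame, sets: GeneSetCollection):
        """Train on a study: normalization, selection and ensemble.

        ``matrix`` is exon- or gene-level log2 intensities; ``meta`` holds
        class and batch; ``sets`` is the gene-set collection.  All label
        use happens here.
        """
        cfg = self.config
        m = preprocess.summarize_exons(matrix)
        self.marker_model = preprocess.fit_marker_model(
            m, meta, marker_genes=cfg.marker_genes
        )
        ratios = preprocess.normalize_log2ratio(m, model=self.marker_model)

        diff = feat.differential_stats(ratios, meta)
        diff = feat.gsa_scores(diff, sets, ratios, meta,
                               n_perm=cfg.n_perm, seed=cfg.seed)
        self.diff = diff

        selected = list(diff.selected_sets(cfg.gsa_regime, cfg.gsa_threshold))
        if not selected:
            # degenerate training set: no set passes the score threshold;
            # keep the pipeline total by falling back to the single most
            # extreme set under the active regime
            s = diff.set_scores["score"]
            ranked = s.sort_values() if cfg.gsa_regime == "down_only" else (-s.abs()).sort_values()
            selected = [ranked.index[0]]
            logger.warning("no gene set passed the score threshold; "
                           "falling back to %s", selected[0])
        self.selected_sets = selected
        directions = diff.set_scores["direction"].to_dict()

        if cfg.feature_kind == "gene":
            try:
                self.selected_genes = feat.filter_genes_in_sets(
                    sets.subset(selected), directions, diff, alpha=cfg.gene_alpha
                )
            except ValueError:
                members = sorted({g for n in selected for g in sets[n]
                                  if g in diff.genes.index})
                by_p = diff.genes.loc[members, "p"].sort_values()
                self.selected_genes = list(by_p.index[: max(1, min(20, len(by_p)))])
                logger.warning("individual differential filter empty; "
                               "falling back to %d best member genes",
                               len(self.selected_genes))

        table = self._build_features(ratios, sets)
        labels = list(meta.loc[table.sample_ids, "class"])

        if cfg.use_shadow_selection:
            ranked = shadow_select.compute_fwer(
                table, labels, backend=cfg.shadow_backend,
                n_trees=cfg.n_trees, n_reps=cfg.shadow_reps, seed=cfg.seed,
            )
            self.ranked_ids = shadow_select.rank_for_ensemble(ranked)
        else:
            if cfg.feature_kind == "gene_set":
                order = diff.set_scores.loc[self.selected_sets, "score"].abs()
                self.ranked_ids = list(order.sort_values(ascending=False).index)
            else:
                order = diff.genes.loc[self.selected_genes, "p"]
                self.ranked_ids = list(order.sort_values().index)

        self._train_features = table.subset_features(self.ranked_ids)
        self._train_labels = labels
        self.ensemble = classify.train_ensemble(
            table, labels, self.ranked_ids,
            kernel_params=cfg.kernel_params, seed=cfg.seed,
        )
        self._sets = sets
        return self

    # -- prediction --------------------------------------------------------

    def transform(self, matrix) -> FeatureTable:
        """Features for new samples using the frozen training selections."""
        if self.ensemble is None:
            raise RuntimeError("pipeline is not fitted")
        ratios = self._to_ratios(matrix)
        table = self._build_features(ratios, self._sets)
        return table.subset_features(self.ranked_ids)

    def predict(self, matrix) -> classify.PredictionResult:
        """Static (one-shot) ensemble prediction."""
        return classify.predict_ensemble(self.ensemble, self.transform(matrix))

    def predict_active(self, matrix, oracle) -> list:
        """Blinded minimum-entropy active-learning prediction transcript.

        ``oracle`` maps sample id -> true label (a mapping or callable); it
        is consulted only *after* each prediction is committed.
        """
        table = self.transform(matrix)
        return active_learn.active_loop(
            self._train_features, self._train_labels, table, oracle,
            ranked_ids=self.ranked_ids, kernel_params=self.config.kernel_params,
            seed=self.config.seed,
        )

    def predict_labels(self, matrix, oracle=None) -> pd.Series:
        """Hard labels, via the active loop when configured, else static."""
        if self.config.use_active_learning and oracle is not None:
            transcript = self.predict_active(matrix, oracle)
            return pd.Series({e.sample_id: e.predicted_label for e in transcript})
        return self.predict(matrix).label


# ---------------------------------------------------------------------------
# cross-validation adapter
# ---------------------------------------------------------------------------

def make_cv_fit_predict(
    matrix, meta: pd.DataFrame, sets: GeneSetCollection, config: RunConfig
) -> Callable:
    """Adapter for :func:`indicell.evaluate.cv_harness`.

    Returns ``fit_predict(train_ids, train_labels, test_ids)`` that trains
    a fresh pipeline on the training split only (marker model included)
    and predicts the held-out split, honouring the leakage contract.
    """
    gene_matrix = preprocess.summarize_exons(matrix)

    def fit_predict(train_ids, train_labels, test_ids):
        train_m = gene_matrix.subset_samples(train_ids)
        train_meta = meta.loc[list(train_ids)].copy()
        train_meta["class"] = list(train_labels)
        pipe = DiseaseClassifierPipeline(config).fit(train_m, train_meta, sets)
        pred = pipe.predict(gene_matrix.subset_samples(test_ids))
        selected = (pipe.selected_genes if config.feature_kind == "gene"
                    else pipe.selected_sets)
        return list(pred.label), list(selected)

    return fit_predict


# ---------------------------------------------------------------------------
# 16-configuration grid
# ---------------------------------------------------------------------------

def run_grid(
    train_matrix,
    train_meta: pd.DataFrame,
    sets: GeneSetCollection,
    offsig_matrix,
    offsig_meta: pd.DataFrame,
    test_matrix=None,
    test_meta: pd.DataFrame | None = None,
    base_config: RunConfig = RunConfig(),
) -> pd.DataFrame:
    """Train all 16 configurations; tally off-signature non-carrier calls.

    For each configuration the pipeline is trained on the full training
    study and used to classify the off-signature cohort (true label:
    non-carrier of the trained signature) and, optionally, an independent
    true-signature test cohort.  Returns one row per configuration with
    the off-signature non-carrier fraction ("hunt tally" of Fig-style
    reporting) and test-set metrics.
    """
    rows = []
    for cfg in sixteen_grid(base_config):
        pipe = DiseaseClassifierPipeline(cfg).fit(train_matrix, train_meta, sets)

        oracle = {s: "non-carrier" for s in offsig_meta.index}
        off_labels = pipe.predict_labels(offsig_matrix, oracle)
        off_frac = float((off_labels == "non-carrier").mean())

        row = {
            "gsa_regime": cfg.gsa_regime,
            "feature_kind": cfg.feature_kind,
            "use_shadow_selection": cfg.use_shadow_selection,
            "use_active_learning": cfg.use_active_learning,
            "n_features": len(pipe.ranked_ids),
            "offsig_noncarrier_frac": off_frac,
            "config_hash": cfg.config_hash(),
        }
        if test_matrix is not None and test_meta is not None:
            oracle = test_meta["class"].to_dict()
            pred = pipe.predict_labels(test_matrix, oracle)
            actual = test_meta.loc[pred.index, "class"]
            m = evaluate.confusion_metrics(pred.to_numpy(), actual.to_numpy())
            row.update({
                "test_accuracy": m.accuracy,
                "test_sensitivity": m.sensitivity,
                "test_specificity": m.specificity,
                "disease_miss_frac": (1.0 - m.sensitivity
                                      if np.isfinite(m.sensitivity) else np.nan),
            })
        rows.append(row)
    return pd.DataFrame(rows)
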