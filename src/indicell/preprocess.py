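"""Loading, exon summarization, array QC and marker-gene normalization.

The assay measures the transcriptional response of standardized indicator
cells exposed to serum/plasma.  Raw exon-level log2 intensities (already
background-corrected and summarized upstream) are reduced to gene level by
averaging exons, screened for low-quality arrays with an iterative Grubbs
test on average within-batch Pearson correlations, and converted to log2
expression ratios against the expression *predicted* by a linear model of
four batch-tracking marker genes fit on reference (non-carrier) arrays.
Subtracting the prediction on the log2 scale is the log2 of the
observed/predicted quotient and removes the between-batch component that
the marker genes encode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("indicell")

#: Marker genes used to track batch state of motor-neuron indicator cells.
#: These are defaults; any gene list present in the matrix may be used.
DEFAULT_MARKER_GENES = ("Olig2", "Mnx1", "Isl1", "Lhx3")

#: Recognized values of the sample class column.
KNOWN_CLASSES = ("carrier", "non-carrier", "unknown", "off-signature", "AD", "normal")

LOG2_INTENSITY = "log2_intensity"
LOG2_RATIO = "log2_ratio"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExonMatrix:
    """Exon x sample grid of normalized log2 intensities.

    ``values`` is indexed by exon id; ``exon_to_gene`` maps every exon id to
    exactly one gene id.
    """

    values: pd.DataFrame
    exon_to_gene: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate exon ids in exon matrix")
        missing = self.values.index.difference(self.exon_to_gene.index)
        if len(missing):
            raise ValueError(f"exons without gene assignment: {list(missing[:5])}")
        self.exon_to_gene = self.exon_to_gene.loc[self.values.index]

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class ExpressionMatrix:
    """Gene x sample numeric grid with a declared scale.

    ``scale`` is ``"log2_intensity"`` for normalized intensities and
    ``"log2_ratio"`` after division by a predicted/baseline profile.
    Consumers check the scale rather than guessing from the values.
    """

    values: pd.DataFrame
    scale: str = LOG2_INTENSITY

    def __post_init__(self) -> None:
        if self.scale not in (LOG2_INTENSITY, LOG2_RATIO):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids in expression matrix")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)], self.scale)


@dataclass
class MarkerModel:
    """Per-gene OLS of expression on marker-gene expression plus intercept.

    Fit on reference (non-carrier) arrays; doubles as the standard
    non-carrier expression profile used to turn new arrays into ratios.
    ``coefficients`` has one row per target gene with columns
    ``["intercept", marker_1, ..., marker_k]``.
    """

    marker_gene_ids: tuple
    coefficients: pd.DataFrame
    reference_sample_ids: tuple

    def predict(self, m: ExpressionMatrix) -> pd.DataFrame:
        """Predicted log2 intensity for every modelled gene in ``m``'s samples."""
        markers = m.values.loc[list(self.marker_gene_ids)]
        design = np.vstack([np.ones(markers.shape[1]), markers.to_numpy()])
        pred = self.coefficients.to_numpy() @ design
        return pd.DataFrame(pred, index=self.coefficients.index, columns=m.sample_ids)


@dataclass
class QcReport:
    """Outcome of the correlation/Grubbs array screen."""

    avg_pearson_r: pd.Series
    grubbs_stats: list = field(default_factory=list)  # (batch, sample, G, G_crit)
    removed_sample_ids: tuple = ()
    skipped_batches: tuple = ()


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def read_expression_tsv(path: str | Path) -> ExonMatrix | ExpressionMatrix:
    """Read an expression TSV.

    Layout: header row of sample ids; first column exon or gene id; an
    optional second column ``gene_id`` marks an exon-level file.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.columns.size and df.columns[0] == "gene_id":
        exon_to_gene = df["gene_id"].astype(str)
        values = df.drop(columns="gene_id").astype(float)
        return ExonMatrix(values=values, exon_to_gene=exon_to_gene)
    return ExpressionMatrix(values=df.astype(float), scale=LOG2_INTENSITY)


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata TSV (sample_id, class, batch, apoe4_count)."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dups}")
    meta = meta.set_index("sample_id", drop=False)
    if "apoe4_count" not in meta.columns:
        meta["apoe4_count"] = np.nan
    return meta


def load_study(
    expression_path: str | Path,
    meta_path: str | Path,
    gmt_path: str | Path | None = None,
):
    """Load a study bundle and align samples and gene sets to the matrix.

    Returns ``(matrix, meta, sets)`` where ``matrix`` is exon- or gene-level
    depending on the file, ``meta`` is indexed by sample id in matrix column
    order, and ``sets`` (or None) has unresolvable member genes dropped with
    a logged warning.  Metadata that does not cover every matrix column is a
    hard failure.
    """
    matrix = read_expression_tsv(expression_path)
    meta = read_sample_meta(meta_path)

    cols = matrix.values.columns
    if cols.duplicated().any():
        raise ValueError("duplicate sample ids in expression matrix")
    missing = cols.difference(meta.index)
    if len(missing):
        raise ValueError(f"samples missing from metadata: {sorted(missing)}")
    extra = meta.index.difference(cols)
    if len(extra):
        logger.warning("metadata rows without matrix columns dropped: %s", sorted(extra))
    meta = meta.loc[cols]

    sets = None
    if gmt_path is not None:
        from .features import GeneSetCollection  # local import: avoids module cycle

        sets = GeneSetCollection.from_gmt(gmt_path)
        if isinstance(matrix, ExonMatrix):
            known = pd.Index(matrix.exon_to_gene.unique())
        else:
            known = matrix.gene_ids
        sets = sets.restrict_to(known, warn=True)
    return matrix, meta, sets


# ---------------------------------------------------------------------------
# exon summarization
# ---------------------------------------------------------------------------

def summarize_exons(m: ExonMatrix | ExpressionMatrix) -> ExpressionMatrix:
    """Gene expression = arithmetic mean of the gene's exons, per sample.

    Gene-level input passes through unchanged, so the step is idempotent.
    """
    if isinstance(m, ExpressionMatrix):
        return m
    gene_values = m.values.groupby(m.exon_to_gene, sort=True).mean()
    gene_values.index.name = m.values.index.name or "gene_id"
    return ExpressionMatrix(values=gene_values, scale=LOG2_INTENSITY)


# ---------------------------------------------------------------------------
# array QC
# ---------------------------------------------------------------------------

def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value for sample size ``n``."""
    t = stats.t.isf(alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))


def _mean_pearson_r(values: pd.DataFrame) -> pd.Series:
    """Each array's mean Pearson r against the other arrays in the group."""
    r = np.corrcoef(values.to_numpy().T)
    n = r.shape[0]
    # exclude the self-correlation from the average
    avg = (r.sum(axis=1) - np.diag(r)) / (n - 1)
    return pd.Series(avg, index=values.columns)


def qc_outliers(
    m: ExpressionMatrix,
    meta: pd.DataFrame,
    alpha: float = 0.05,
    within_batch: bool = True,
    max_removed_frac: float = 0.2,
) -> QcReport:
    """Flag outlier arrays via a two-sided Grubbs test on average Pearson r.

    Arrays are compared within their batch (``within_batch=False`` compares
    against the whole cohort).  The single most extreme average-correlation
    score is tested and, if rejected at ``alpha``, removed and the test
    repeated, until no rejection, fewer than 3 arrays remain, or
    ``max_removed_frac`` of the group has been removed.  Groups with fewer
    than 3 arrays are skipped with a warning.
    """
    if within_batch:
        groups = [(b, list(idx)) for b, idx in meta.groupby("batch").groups.items()]
    else:
        groups = [("all", list(m.sample_ids))]

    removed: list[str] = []
    skipped: list = []
    grubbs_log: list[tuple] = []
    all_scores = {}

    for batch, samples in groups:
        samples = [s for s in samples if s in m.sample_ids]
        if len(samples) < 3:
            logger.warning("QC: batch %r has <3 arrays, skipped", batch)
            skipped.append(batch)
            continue
        current = list(samples)
        all_scores.update(_mean_pearson_r(m.values[current]).to_dict())
        max_removals = max(1, int(np.floor(max_removed_frac * len(samples))))
        n_removed = 0
        while len(current) >= 3 and n_removed < max_removals:
            scores = _mean_pearson_r(m.values[current])
            sd = scores.std(ddof=1)
            if sd == 0 or not np.isfinite(sd):
                break  # identical scores: nothing to test
            dev = (scores - scores.mean()).abs()
            worst = dev.idxmax()
            g = dev.loc[worst] / sd
            g_crit = grubbs_critical(len(current), alpha)
            grubbs_log.append((batch, worst, float(g), float(g_crit)))
            if g <= g_crit:
                break
            removed.append(worst)
            current.remove(worst)
            n_removed += 1

    return QcReport(
        avg_pearson_r=pd.Series(all_scores),
        grubbs_stats=grubbs_log,
        removed_sample_ids=tuple(removed),
        skipped_batches=tuple(skipped),
    )


# ---------------------------------------------------------------------------
# marker-gene linear model
# ---------------------------------------------------------------------------

def fit_marker_model(
    m: ExpressionMatrix,
    meta: pd.DataFrame,
    marker_genes: Sequence[str] = DEFAULT_MARKER_GENES,
    reference_class: str = "non-carrier",
) -> MarkerModel:
    """OLS of every non-marker gene on the marker genes over reference arrays.

    References are the ``reference_class`` samples; at least
    ``len(marker_genes) + 2`` are required so the design has spare degrees
    of freedom.  A rank-deficient (collinear) marker design falls back to
    the minimum-norm least-squares solution with a warning.
    """
    marker_genes = tuple(marker_genes)
    missing = [g for g in marker_genes if g not in m.gene_ids]
    if missing:
        raise ValueError(f"marker genes absent from matrix: {missing}")
    refs = meta.index[meta["class"] == reference_class]
    refs = [s for s in refs if s in m.sample_ids]
    n_params = len(marker_genes) + 1
    if len(refs) < n_params + 1:
        raise ValueError(
            f"need at least {n_params + 1} {reference_class!r} reference samples "
            f"to fit {n_params} parameters, got {len(refs)}"
        )

    markers = m.values.loc[list(marker_genes), refs].to_numpy()
    design = np.vstack([np.ones(len(refs)), markers]).T  # refs x (1+k)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        logger.warning(
            "marker design is rank deficient (rank %d < %d); "
            "using minimum-norm solution", rank, design.shape[1]
        )
    targets = m.values.index.difference(marker_genes)
    y = m.values.loc[targets, refs].to_numpy().T  # refs x genes
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    coefficients = pd.DataFrame(
        coef.T, index=targets, columns=["intercept", *marker_genes]
    )
    return MarkerModel(
        marker_gene_ids=marker_genes,
        coefficients=coefficients,
        reference_sample_ids=tuple(refs),
    )


def normalize_log2ratio(
    m: ExpressionMatrix,
    model: MarkerModel | None = None,
    baseline: pd.Series | None = None,
) -> ExpressionMatrix:
    """Convert log2 intensities to log2 ratios over a predicted profile.

    value = observed log2 - predicted log2, i.e. the log2 of the
    linear-scale quotient observed/predicted.  The predictor is either the
    marker-gene model (batch-corrected reference profile) or, for assays
    with unexposed-cell controls, a fixed per-gene ``baseline`` profile
    (e.g. the mean of no-serum control arrays).  Genes whose prediction is
    non-finite are dropped with a warning.
    """
    if m.scale != LOG2_INTENSITY:
        raise ValueError(f"expected scale {LOG2_INTENSITY!r}, got {m.scale!r}")
    if (model is None) == (baseline is None):
        raise ValueError("provide exactly one of model= or baseline=")

    if model is not None:
        predicted = model.predict(m)
        observed = m.values.loc[predicted.index]
    else:
        common = m.gene_ids.intersection(baseline.index)
        observed = m.values.loc[common]
        predicted = pd.DataFrame(
            np.tile(baseline.loc[common].to_numpy()[:, None], (1, observed.shape[1])),
            index=common, columns=observed.columns,
        )

    ratios = observed - predicted
    bad = ~np.isfinite(ratios.to_numpy()).all(axis=1)
    if bad.any():
        logger.warning("dropping %d genes with non-finite predictions", int(bad.sum()))
        ratios = ratios.loc[~bad]
    return ExpressionMatrix(values=ratios, scale=LOG2_RATIO)
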