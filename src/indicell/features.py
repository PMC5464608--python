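"""Classifier features from normalized log2 expression ratios.

Two feature families are supported, mirroring the two classifier designs
the platform uses:

* **Gene-set features** — per-set differential scores via the maxmean
  gene-set statistic with permutation restandardization, thresholded at
  +/-1, then one aggregate feature per selected set (the mean member-gene
  log2 ratio per sample).
* **Gene features** — either the member genes of selected sets that are
  individually differential (the gene-expression classifier), or genes
  ranked by a joint score combining fold change, t-test p-value and the
  best gene-set score of any set containing the gene.

A label-blind co-expression clustering provides *de novo* cluster-mean
features, and Sturges binning of family-wise error rates removes features
whose shadow-based FWER falls in the bin containing 1.0.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .preprocess import LOG2_RATIO, ExpressionMatrix

logger = logging.getLogger("indicell")

FEATURE_KINDS = ("gene_ratio", "set_mean", "cluster_mean", "covariate")


# ---------------------------------------------------------------------------
# gene-set collection
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene-id sets (GO/KEGG/REACTOME-style or synthetic)."""

    sets: dict
    source: str = "unknown"

    def __post_init__(self) -> None:
        self.sets = {name: frozenset(members) for name, members in self.sets.items()}
        empty = [name for name, members in self.sets.items() if not members]
        if empty:
            raise ValueError(f"empty gene sets: {empty[:5]}")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def items(self):
        return self.sets.items()

    def subset(self, names: Iterable[str]) -> "GeneSetCollection":
        return GeneSetCollection({n: self.sets[n] for n in names}, self.source)

    def restrict_to(self, genes: pd.Index, warn: bool = False) -> "GeneSetCollection":
        """Drop member genes not in ``genes``; drop sets emptied by that."""
        genes = set(genes)
        kept, dropped_members, dropped_sets = {}, 0, []
        for name, members in self.sets.items():
            resolved = members & genes
            dropped_members += len(members) - len(resolved)
            if resolved:
                kept[name] = resolved
            else:
                dropped_sets.append(name)
        if warn and (dropped_members or dropped_sets):
            logger.warning(
                "gene sets: dropped %d unresolvable member genes and %d empty sets",
                dropped_members, len(dropped_sets),
            )
        return GeneSetCollection(kept, self.source)

    @classmethod
    def from_gmt(cls, path: str | Path, source: str = "gmt") -> "GeneSetCollection":
        sets = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            name, _desc, *members = line.rstrip("\n").split("\t")
            sets[name] = frozenset(m for m in members if m)
        return cls(sets, source)

    def to_gmt(self, path: str | Path, descriptions: Mapping[str, str] | None = None) -> None:
        descriptions = descriptions or {}
        with open(path, "w") as fh:
            for name, members in self.sets.items():
                desc = descriptions.get(name, "na")
                fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# differential statistics
# ---------------------------------------------------------------------------

@dataclass
class DifferentialResult:
    """Per-gene Welch statistics and (optionally) per-set maxmean scores.

    ``genes`` columns: fold_change (disease - control class-mean difference
    in log2 units), t, p, flagged (zero-variance convention applied).
    ``set_scores`` columns (after :func:`gsa_scores`): raw_score, score
    (restandardized), direction.
    """

    genes: pd.DataFrame
    disease_class: str
    control_class: str
    set_scores: pd.DataFrame | None = None

    def selected_sets(self, regime: str = "down_only", threshold: float = 1.0) -> pd.Index:
        """Sets passing the published score-threshold regimes."""
        if self.set_scores is None:
            raise ValueError("gsa_scores has not been run")
        s = self.set_scores["score"]
        if regime == "down_only":
            return s.index[s <= -threshold]
        if regime == "two_sided":
            return s.index[s.abs() >= threshold]
        raise ValueError(f"unknown regime {regime!r}")


def _welch_rows(x: np.ndarray, y: np.ndarray):
    """Row-wise Welch t-test; zero-variance rows get t=0, p=1, flag."""
    nx, ny = x.shape[1], y.shape[1]
    mx, my = x.mean(axis=1), y.mean(axis=1)
    vx, vy = x.var(axis=1, ddof=1), y.var(axis=1, ddof=1)
    se2 = vx / nx + vy / ny
    flagged = se2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mx - my) / np.sqrt(se2)
        df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    t = np.where(flagged, 0.0, t)
    df = np.where(flagged, 1.0, df)
    p = np.where(flagged, 1.0, 2.0 * stats.t.sf(np.abs(t), df))
    return mx - my, t, p, flagged


def differential_stats(
    ratios: ExpressionMatrix,
    meta: pd.DataFrame,
    disease_class: str = "carrier",
    control_class: str = "non-carrier",
) -> DifferentialResult:
    """Welch two-sample t per gene; fold change = difference of class means."""
    if ratios.scale != LOG2_RATIO:
        raise ValueError(f"expected scale {LOG2_RATIO!r}, got {ratios.scale!r}")
    d_ids = meta.index[meta["class"] == disease_class].intersection(ratios.sample_ids)
    c_ids = meta.index[meta["class"] == control_class].intersection(ratios.sample_ids)
    if len(d_ids) < 2 or len(c_ids) < 2:
        raise ValueError("need at least 2 samples per class")
    fc, t, p, flagged = _welch_rows(
        ratios.values[list(d_ids)].to_numpy(), ratios.values[list(c_ids)].to_numpy()
    )
    genes = pd.DataFrame(
        {"fold_change": fc, "t": t, "p": p, "flagged": flagged}, index=ratios.gene_ids
    )
    return DifferentialResult(genes=genes, disease_class=disease_class,
                              control_class=control_class)


# ---------------------------------------------------------------------------
# gene-set scores (maxmean with permutation restandardization)
# ---------------------------------------------------------------------------

def maxmean_statistic(scores: np.ndarray, size: int | None = None) -> float:
    """Maxmean set statistic over member gene scores.

    Mean of positive parts and mean of negative parts are both taken over
    the set size; the statistic is the larger magnitude, signed.
    """
    n = size if size is not None else len(scores)
    pos = np.clip(scores, 0, None).sum() / n
    neg = np.clip(-scores, 0, None).sum() / n
    return float(pos) if pos >= neg else float(-neg)


def _set_scores_from_gene_scores(
    gene_scores: np.ndarray, member_idx: list[np.ndarray]
) -> np.ndarray:
    out = np.empty(len(member_idx))
    for i, idx in enumerate(member_idx):
        out[i] = maxmean_statistic(gene_scores[idx])
    return out


def gsa_scores(
    diff: DifferentialResult,
    sets: GeneSetCollection,
    ratios: ExpressionMatrix,
    meta: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    restandardize: bool = True,
) -> DifferentialResult:
    """Maxmean score per set, restandardized against label permutations.

    The raw maxmean of member-gene t-scores is centred and scaled by the
    mean/SD of the same statistic under ``n_perm`` random label
    permutations.  Sets whose members were all filtered from the matrix are
    excluded.  Returns a new :class:`DifferentialResult` carrying
    ``set_scores``; selection masks for the two published regimes come from
    :meth:`DifferentialResult.selected_sets`.
    """
    if len(sets) == 0:
        raise ValueError("empty gene-set collection")
    gene_index = diff.genes.index
    pos = {g: i for i, g in enumerate(gene_index)}
    names, member_idx, dropped = [], [], []
    for name, members in sets.items():
        idx = np.array(sorted(pos[g] for g in members if g in pos), dtype=int)
        if idx.size == 0:
            dropped.append(name)
            continue
        names.append(name)
        member_idx.append(idx)
    if dropped:
        logger.warning("gsa: %d sets had no resolvable members and were excluded",
                       len(dropped))

    observed = diff.genes["t"].to_numpy()
    raw = _set_scores_from_gene_scores(observed, member_idx)

    if restandardize:
        d_ids = meta.index[meta["class"] == diff.disease_class].intersection(ratios.sample_ids)
        c_ids = meta.index[meta["class"] == diff.control_class].intersection(ratios.sample_ids)
        data = ratios.values[list(d_ids) + list(c_ids)].to_numpy()
        n_d = len(d_ids)
        rng = np.random.default_rng(seed)
        perm_scores = np.empty((n_perm, len(names)))
        n_total = data.shape[1]
        for b in range(n_perm):
            order = rng.permutation(n_total)
            _, t_perm, _, _ = _welch_rows(data[:, order[:n_d]], data[:, order[n_d:]])
            perm_scores[b] = _set_scores_from_gene_scores(t_perm, member_idx)
        mean = perm_scores.mean(axis=0)
        sd = perm_scores.std(axis=0, ddof=1)
        sd[sd == 0] = np.nan
        score = (raw - mean) / sd
    else:
        score = raw.copy()

    set_scores = pd.DataFrame(
        {"raw_score": raw, "score": score, "direction": np.where(score >= 0, 1, -1)},
        index=pd.Index(names, name="set"),
    ).dropna(subset=["score"])
    return DifferentialResult(
        genes=diff.genes, disease_class=diff.disease_class,
        control_class=diff.control_class, set_scores=set_scores,
    )


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Sample x feature grid with per-feature kind and provenance."""

    values: pd.DataFrame
    kinds: pd.Series
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate feature ids")
        if self.values.isna().any().any():
            raise ValueError("missing values in feature table")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    def subset_features(self, ids: Sequence[str]) -> "FeatureTable":
        ids = list(ids)
        return FeatureTable(
            self.values[ids], self.kinds.loc[ids],
            {k: v for k, v in self.provenance.items() if k in set(ids)},
        )

    def concat(self, other: "FeatureTable") -> "FeatureTable":
        clash = self.feature_ids.intersection(other.feature_ids)
        if len(clash):
            raise ValueError(f"duplicate feature ids on concat: {sorted(clash)}")
        return FeatureTable(
            pd.concat([self.values, other.values.loc[self.sample_ids]], axis=1),
            pd.concat([self.kinds, other.kinds]),
            {**self.provenance, **other.provenance},
        )

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")
        sidecar = Path(path).with_suffix(Path(path).suffix + ".provenance.json")
        sidecar.write_text(json.dumps(
            {f: sorted(v) if isinstance(v, (set, frozenset)) else v
             for f, v in self.provenance.items()}, indent=1))


def aggregate_set_features(
    ratios: ExpressionMatrix, sets_selected: GeneSetCollection
) -> FeatureTable:
    """One feature per set: the mean member-gene log2 ratio per sample."""
    if len(sets_selected) == 0:
        raise ValueError("no selected sets")
    cols = {}
    prov = {}
    for name, members in sets_selected.items():
        present = [g for g in members if g in ratios.gene_ids]
        cols[name] = ratios.values.loc[present].mean(axis=0)
        prov[name] = frozenset(present)
    values = pd.DataFrame(cols)
    kinds = pd.Series("set_mean", index=values.columns)
    return FeatureTable(values=values, kinds=kinds, provenance=prov)


def gene_features(ratios: ExpressionMatrix, gene_ids: Sequence[str]) -> FeatureTable:
    """Individual gene log2 ratios as features."""
    gene_ids = list(gene_ids)
    values = ratios.values.loc[gene_ids].T
    kinds = pd.Series("gene_ratio", index=values.columns)
    return FeatureTable(values=values, kinds=kinds,
                        provenance={g: frozenset([g]) for g in gene_ids})


def filter_genes_in_sets(
    sets_selected: GeneSetCollection,
    set_directions: Mapping[str, int],
    diff: DifferentialResult,
    alpha: float = 0.05,
) -> list[str]:
    """Members of selected sets that are individually differential.

    Keeps genes with Welch p < ``alpha`` whose fold-change sign matches the
    direction of at least one selected set containing them.
    """
    genes = diff.genes
    kept = set()
    for name, members in sets_selected.items():
        direction = set_directions[name]
        for g in members:
            if g not in genes.index:
                continue
            row = genes.loc[g]
            if row["p"] < alpha and np.sign(row["fold_change"]) == direction:
                kept.add(g)
    if not kept:
        raise ValueError(
            "no genes pass the individual differential filter; "
            "consider a larger alpha or different set selection"
        )
    return sorted(kept)


# ---------------------------------------------------------------------------
# joint gene score (gene-feature ranking for the human assay)
# ---------------------------------------------------------------------------

@dataclass
class JointScore:
    """Percentile ranks of three per-gene metrics and their geometric mean."""

    table: pd.DataFrame  # columns: fc_rank, p_rank, gsa_rank, score

    def top_genes(self, n: int) -> list[str]:
        return list(self.table.sort_values("score", ascending=False).index[:n])


def _percentile_rank(values: pd.Series) -> pd.Series:
    """Ascending percentile rank in (0, 1]; larger value = larger rank.

    Ties take the maximum rank so a gene tied for best still ranks 1.0.
    """
    return values.rank(method="max", ascending=True) / len(values)


def ad_joint_score(diff: DifferentialResult, sets: GeneSetCollection | None = None) -> JointScore:
    """Rank genes by a joint score equally weighting three metrics.

    Metrics (better = larger rank): |fold change|, significance of the
    Welch test (smaller p), and |best set score| over sets containing the
    gene.  Each is converted to an ascending percentile rank and the joint
    score is the geometric mean of the three.  Genes in no set receive the
    neutral rank 0.5 for the set metric.
    """
    genes = diff.genes
    fc_rank = _percentile_rank(genes["fold_change"].abs())
    p_rank = _percentile_rank(-genes["p"])

    best: dict[str, float] = {}
    if diff.set_scores is not None and sets is not None:
        gene_universe = set(genes.index)
        for name in diff.set_scores.index:
            s = abs(float(diff.set_scores.loc[name, "score"]))
            for g in sets[name]:
                if g in gene_universe and s > best.get(g, -np.inf):
                    best[g] = s
    gsa_rank = pd.Series(0.5, index=genes.index)
    if best:
        covered = pd.Series(best)
        gsa_rank.loc[covered.index] = _percentile_rank(covered)

    score = (fc_rank * p_rank * gsa_rank) ** (1.0 / 3.0)
    table = pd.DataFrame({
        "fc_rank": fc_rank, "p_rank": p_rank, "gsa_rank": gsa_rank, "score": score,
    })
    return JointScore(table=table)


# ---------------------------------------------------------------------------
# co-expression cluster features
# ---------------------------------------------------------------------------

def cluster_features(
    ratios: ExpressionMatrix,
    size_bounds: tuple[int, int] = (5, 50),
    max_genes: int = 2000,
) -> FeatureTable:
    """Label-blind co-expression clusters as aggregate features.

    Average-linkage hierarchical clustering on the 1 - Pearson correlation
    distance between genes; the tree is cut at the height that maximizes
    the number of clusters whose sizes fall within ``size_bounds``, and one
    feature per in-bounds cluster is emitted as the per-sample mean member
    ratio.  For tractability only the ``max_genes`` most variable genes are
    clustered.  No class labels are consulted at any point.
    """
    if ratios.scale != LOG2_RATIO:
        raise ValueError(f"expected scale {LOG2_RATIO!r}, got {ratios.scale!r}")
    values = ratios.values
    if values.shape[0] > max_genes:
        order = values.var(axis=1).sort_values(ascending=False)
        values = values.loc[order.index[:max_genes]]

    x = values.to_numpy()
    sd = x.std(axis=1)
    keep = sd > 0
    values, x = values.loc[keep], x[keep]
    if values.shape[0] < size_bounds[0]:
        logger.warning("cluster_features: too few variable genes, empty table")
        return FeatureTable(pd.DataFrame(index=ratios.sample_ids),
                            pd.Series(dtype=object), {})

    corr = np.corrcoef(x)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    from scipy.spatial.distance import squareform
    z = linkage(squareform(dist, checks=False), method="average")

    heights = np.unique(z[:, 2])
    candidates = np.quantile(heights, np.linspace(0.05, 0.95, 19))
    best_labels, best_count = None, -1
    for h in candidates:
        labels = fcluster(z, t=h, criterion="distance")
        sizes = np.bincount(labels)
        n_ok = int(((sizes >= size_bounds[0]) & (sizes <= size_bounds[1])).sum())
        if n_ok > best_count:
            best_count, best_labels = n_ok, labels

    if best_count <= 0:
        logger.warning("cluster_features: no cluster within size bounds %s", size_bounds)
        return FeatureTable(pd.DataFrame(index=ratios.sample_ids),
                            pd.Series(dtype=object), {})

    cols, prov = {}, {}
    sizes = np.bincount(best_labels)
    k = 0
    for lab in np.unique(best_labels):
        if not (size_bounds[0] <= sizes[lab] <= size_bounds[1]):
            continue
        k += 1
        members = values.index[best_labels == lab]
        name = f"cluster_{k:03d}"
        cols[name] = values.loc[members].mean(axis=0)
        prov[name] = frozenset(members)
    table = pd.DataFrame(cols)
    return FeatureTable(table, pd.Series("cluster_mean", index=table.columns), prov)


# ---------------------------------------------------------------------------
# Sturges FWER binning
# ---------------------------------------------------------------------------

def sturges_filter(fwer_values: pd.Series | Mapping[str, float]) -> list:
    """Drop features whose FWER falls in the Sturges bin containing 1.0.

    k = ceil(log2 N) + 1 equal-width bins over [0, 1]; features in the top
    bin [(k-1)/k, 1] are removed.
    """
    fwer = pd.Series(fwer_values, dtype=float)
    n = len(fwer)
    if n == 0:
        return []
    if ((fwer < 0) | (fwer > 1)).any():
        raise ValueError("FWERs must lie in [0, 1]")
    k = int(np.ceil(np.log2(n))) + 1 if n > 1 else 1
    cut = (k - 1) / k
    return list(fwer.index[fwer < cut])
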