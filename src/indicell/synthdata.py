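"""Synthetic serum-response cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage can be tested without external data:

* ~20,000 genes, each measured as several exons (exon value = gene value
  plus an iid Gaussian exon offset with SD = noise_sd/2, exercising the
  mean-summarization step);
* per-batch technical shifts, linearly encoded in four reserved marker
  genes so the marker-model normalization has signal to exploit;
* a disease class whose effect is concentrated in designated responsive
  gene sets (down-regulated by default), balanced batch assignment of
  disease and control samples;
* occasional low-quality arrays simulated by tripling the per-gene noise
  SD (detectable by the average-correlation Grubbs screen);
* an optional "off-signature" second disease cohort perturbing gene sets
  disjoint from the true signature, for specificity testing.

Identical seeds give bit-identical output.  With effect_size = 0 the two
classes are exchangeable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .features import GeneSetCollection
from .preprocess import DEFAULT_MARKER_GENES, ExonMatrix

#: RNG stream tags: study-level parameters, cohort samples, off-signature
#: samples, and follow-up (blind validation) samples.
_STREAM_PARAMS, _STREAM_COHORT, _STREAM_OFFSIG, _STREAM_BLIND = 0, 1, 2, 3


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Study design knobs; defaults emulate the murine serum study design
    (25 samples per class assayed in balanced batches of 6-8, a handful of
    corrupted arrays, an all-down disease signature)."""

    n_genes: int = 20000
    exons_per_gene: tuple = (2, 5)  # inclusive range
    n_gene_sets: int = 200
    set_size_range: tuple = (10, 50)  # inclusive range
    n_responsive_sets: int = 10
    effect_size: float = -0.5  # log2 shift of responsive genes in disease
    noise_sd: float = 0.25  # per-gene Gaussian SD, log2 units
    n_batches: int = 7
    batch_effect_sd: float = 0.3  # log2 units
    marker_coupling: tuple = (1.0, 0.8, 1.2, 0.6)
    n_per_class: int = 25
    n_disease: int | None = None  # imbalance option; None = n_per_class
    n_outlier_arrays: int = 3
    outlier_noise_factor: float = 3.0
    disease_subclass_split: float = 0.5  # preclinical vs early-symptomatic
    direction_mode: str = "down"  # "down" | "mixed"
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.set_size_range
        usable = self.n_genes - len(DEFAULT_MARKER_GENES)
        if hi > usable:
            raise ValueError("set sizes exceed the number of available genes")
        if self.n_responsive_sets > self.n_gene_sets:
            raise ValueError("n_responsive_sets must be <= n_gene_sets")
        if self.n_responsive_sets * hi > usable:
            raise ValueError("responsive sets cannot be made disjoint: too few genes")
        n_total = (self.n_disease or self.n_per_class) + self.n_per_class
        if self.n_batches > n_total:
            raise ValueError("n_batches exceeds the total number of samples")
        if self.n_outlier_arrays > n_total:
            raise ValueError("more outlier arrays than samples")
        if lo < 1 or hi < lo:
            raise ValueError("invalid set_size_range")


@dataclass
class GroundTruth:
    """Oracle for recovery tests: which sets/genes carry the signal."""

    responsive_set_ids: frozenset
    responsive_gene_ids: frozenset
    direction_by_set: dict
    outlier_sample_ids: frozenset

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "responsive_set_ids": sorted(self.responsive_set_ids),
            "responsive_gene_ids": sorted(self.responsive_gene_ids),
            "direction_by_set": self.direction_by_set,
            "outlier_sample_ids": sorted(self.outlier_sample_ids),
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            responsive_set_ids=frozenset(d["responsive_set_ids"]),
            responsive_gene_ids=frozenset(d["responsive_gene_ids"]),
            direction_by_set={k: int(v) for k, v in d["direction_by_set"].items()},
            outlier_sample_ids=frozenset(d["outlier_sample_ids"]),
        )


@dataclass
class _StudyParams:
    """Gene-level population parameters shared by all cohorts of a study."""

    gene_ids: list
    mu: np.ndarray  # baseline log2 intensity per gene
    gamma: np.ndarray  # per-gene batch sensitivity
    marker_idx: np.ndarray
    sets: GeneSetCollection
    responsive_sets: list
    direction_by_set: dict
    gene_pos: dict


def _study_params(config: SyntheticStudyConfig) -> _StudyParams:
    config.validate()
    rng = np.random.default_rng([config.seed, _STREAM_PARAMS])
    markers = list(DEFAULT_MARKER_GENES)
    others = [f"g{i:05d}" for i in range(config.n_genes - len(markers))]
    gene_ids = markers + others
    mu = rng.normal(7.0, 1.0, size=config.n_genes)
    gamma = rng.uniform(0.5, 1.5, size=config.n_genes)
    marker_idx = np.arange(len(markers))
    gene_pos = {g: i for i, g in enumerate(gene_ids)}

    lo, hi = config.set_size_range
    pool = rng.permutation(others)
    cursor = 0
    sets: dict[str, frozenset] = {}
    responsive = []
    direction_by_set = {}
    for i in range(config.n_responsive_sets):
        size = int(rng.integers(lo, hi + 1))
        members = pool[cursor:cursor + size]
        cursor += size
        name = f"SET_R{i:03d}"
        sets[name] = frozenset(members)
        responsive.append(name)
        if config.direction_mode == "mixed":
            direction_by_set[name] = -1 if i % 2 == 0 else 1
        else:
            direction_by_set[name] = -1
    decoy_pool = pool[cursor:]
    for i in range(config.n_gene_sets - config.n_responsive_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(decoy_pool, size=min(size, len(decoy_pool)), replace=False)
        sets[f"SET_N{i:03d}"] = frozenset(members)

    return _StudyParams(
        gene_ids=gene_ids, mu=mu, gamma=gamma, marker_idx=marker_idx,
        sets=GeneSetCollection(sets, source="synthetic"),
        responsive_sets=responsive, direction_by_set=direction_by_set,
        gene_pos=gene_pos,
    )


def _gene_matrix(
    params: _StudyParams,
    config: SyntheticStudyConfig,
    rng: np.random.Generator,
    batch_of_sample: np.ndarray,
    beta: np.ndarray,
    disease_mask: np.ndarray,
    noise_factor: np.ndarray,
    shift: dict | None,
) -> np.ndarray:
    """Gene x sample log2 intensities for one cohort."""
    n_genes, n_samples = len(params.gene_ids), len(batch_of_sample)
    x = params.mu[:, None] + params.gamma[:, None] * beta[batch_of_sample][None, :]
    # markers track the batch shift through fixed coupling, low noise
    coupling = np.asarray(config.marker_coupling, dtype=float)
    x[params.marker_idx, :] = (
        params.mu[params.marker_idx][:, None]
        + coupling[:, None] * beta[batch_of_sample][None, :]
    )
    if shift:
        for gene, delta in shift.items():
            x[params.gene_pos[gene], disease_mask] += delta
    sd = config.noise_sd * noise_factor
    noise = rng.normal(0.0, 1.0, size=(n_genes, n_samples)) * sd[None, :]
    noise[params.marker_idx, :] *= 0.25  # markers are reliably measured
    return x + noise


def _expand_exons(
    gene_values: np.ndarray,
    gene_ids: list,
    sample_ids: list,
    config: SyntheticStudyConfig,
    rng: np.random.Generator,
) -> ExonMatrix:
    lo, hi = config.exons_per_gene
    counts = rng.integers(lo, hi + 1, size=len(gene_ids))
    exon_rows = np.repeat(gene_values, counts, axis=0)
    offsets = rng.normal(0.0, config.noise_sd / 2.0, size=exon_rows.shape)
    exon_ids, exon_genes = [], []
    for g, c in zip(gene_ids, counts):
        for j in range(c):
            exon_ids.append(f"{g}_e{j + 1}")
            exon_genes.append(g)
    values = pd.DataFrame(exon_rows + offsets, index=pd.Index(exon_ids, name="exon_id"),
                          columns=sample_ids)
    return ExonMatrix(values=values,
                      exon_to_gene=pd.Series(exon_genes, index=values.index))


def _signal_shift(params: _StudyParams, config: SyntheticStudyConfig) -> dict:
    shift = {}
    magnitude = abs(config.effect_size)
    for name in params.responsive_sets:
        delta = params.direction_by_set[name] * magnitude
        for g in params.sets[name]:
            shift[g] = delta
    return shift


def _meta_frame(sample_ids, classes, batches, apoe4, subclass) -> pd.DataFrame:
    meta = pd.DataFrame({
        "sample_id": sample_ids, "class": classes, "batch": batches,
        "apoe4_count": apoe4, "subclass": subclass,
    }).set_index("sample_id", drop=False)
    return meta


def generate_cohort(config: SyntheticStudyConfig):
    """Generate the training study: (ExonMatrix, meta, gene sets, truth).

    Disease ("carrier") and control ("non-carrier") samples are paired and
    assigned to batches so each batch assays an equal number of
    randomly-selected samples of each class.  Responsive-set genes are
    shifted by effect_size (times the set direction) in disease samples;
    outlier arrays get ``outlier_noise_factor``-fold noise.
    """
    params = _study_params(config)
    rng = np.random.default_rng([config.seed, _STREAM_COHORT])

    n_d = config.n_disease if config.n_disease is not None else config.n_per_class
    n_c = config.n_per_class
    d_ids = [f"d{i + 1:02d}" for i in range(n_d)]
    c_ids = [f"c{i + 1:02d}" for i in range(n_c)]

    # pair disease and control samples, spread pairs over batches
    d_order = rng.permutation(n_d)
    c_order = rng.permutation(n_c)
    n_pairs = max(n_d, n_c)
    pair_batches = np.concatenate(
        [np.full(len(chunk), b) for b, chunk in
         enumerate(np.array_split(np.arange(n_pairs), config.n_batches))]
    )
    sample_ids, classes, batches = [], [], []
    for p in range(n_pairs):
        b = f"batch{pair_batches[p] + 1}"
        if p < n_d:
            sample_ids.append(d_ids[d_order[p]]); classes.append("carrier"); batches.append(b)
        if p < n_c:
            sample_ids.append(c_ids[c_order[p]]); classes.append("non-carrier"); batches.append(b)

    batch_index = {f"batch{b + 1}": b for b in range(config.n_batches)}
    batch_of_sample = np.array([batch_index[b] for b in batches])
    beta = rng.normal(0.0, config.batch_effect_sd, size=config.n_batches)
    disease_mask = np.array([c == "carrier" for c in classes])

    outliers = rng.choice(len(sample_ids), size=config.n_outlier_arrays, replace=False)
    noise_factor = np.ones(len(sample_ids))
    noise_factor[outliers] = config.outlier_noise_factor

    shift = _signal_shift(params, config)
    gene_values = _gene_matrix(params, config, rng, batch_of_sample, beta,
                               disease_mask, noise_factor, shift)
    exons = _expand_exons(gene_values, params.gene_ids, sample_ids, config, rng)

    n_samples = len(sample_ids)
    apoe4 = np.where(
        disease_mask,
        rng.binomial(2, 0.45, size=n_samples),
        rng.binomial(2, 0.15, size=n_samples),
    )
    sub = np.where(
        disease_mask,
        np.where(rng.random(n_samples) < config.disease_subclass_split,
                 "preclinical", "early_symptomatic"),
        "none",
    )
    meta = _meta_frame(sample_ids, classes, batches, apoe4, sub)

    truth = GroundTruth(
        responsive_set_ids=frozenset(params.responsive_sets),
        responsive_gene_ids=frozenset(
            g for s in params.responsive_sets for g in params.sets[s]
        ),
        direction_by_set=dict(params.direction_by_set),
        outlier_sample_ids=frozenset(np.array(sample_ids)[outliers]),
    )
    return exons, meta, params.sets, truth


def generate_offsignature_cohort(
    config: SyntheticStudyConfig,
    truth: GroundTruth,
    n_samples: int = 6,
    n_perturbed_sets: int | None = None,
):
    """A second disease cohort whose signal avoids the true signature.

    Perturbs gene sets disjoint from ``truth.responsive_set_ids`` (and
    from the responsive genes) by the same effect magnitude, in fresh
    batches.  Class label is "off-signature".  Returns (ExonMatrix, meta);
    the perturbed set names are stored in ``meta.attrs["perturbed_sets"]``.
    """
    params = _study_params(config)
    rng = np.random.default_rng([config.seed, _STREAM_OFFSIG])

    candidates = [
        name for name, members in params.sets.items()
        if name not in truth.responsive_set_ids
        and not (members & truth.responsive_gene_ids)
    ]
    if not candidates:
        raise ValueError("no gene sets disjoint from the true signature")
    k = n_perturbed_sets if n_perturbed_sets is not None else config.n_responsive_sets
    k = min(k, len(candidates))
    chosen = sorted(rng.choice(candidates, size=k, replace=False))

    magnitude = abs(config.effect_size)
    shift = {g: -magnitude for name in chosen for g in params.sets[name]}

    sample_ids = [f"hd{i + 1:02d}" for i in range(n_samples)]
    n_batches = max(1, n_samples // 6)
    batch_of_sample = np.arange(n_samples) % n_batches
    beta = rng.normal(0.0, config.batch_effect_sd, size=n_batches)
    disease_mask = np.ones(n_samples, dtype=bool)
    noise_factor = np.ones(n_samples)

    gene_values = _gene_matrix(params, config, rng, batch_of_sample, beta,
                               disease_mask, noise_factor, shift)
    exons = _expand_exons(gene_values, params.gene_ids, sample_ids, config, rng)
    meta = _meta_frame(
        sample_ids, ["off-signature"] * n_samples,
        [f"offsig_batch{b + 1}" for b in batch_of_sample],
        rng.binomial(2, 0.15, size=n_samples), ["none"] * n_samples,
    )
    meta.attrs["perturbed_sets"] = list(chosen)
    return exons, meta


def generate_blind_cohort(
    config: SyntheticStudyConfig,
    n_per_class: int = 6,
    batch_shift_sd: float | None = None,
):
    """An independent validation cohort from the same study population.

    New samples carry the true disease signature but are assayed in fresh
    batches with newly drawn batch shifts (``batch_shift_sd`` defaults to
    the study's batch_effect_sd) — the train/test shift scenario the
    active-learning loop is meant to absorb.  Returns (ExonMatrix, meta).
    """
    params = _study_params(config)
    rng = np.random.default_rng([config.seed, _STREAM_BLIND])

    sample_ids, classes = [], []
    for i in range(n_per_class):
        sample_ids.append(f"vd{i + 1:02d}"); classes.append("carrier")
        sample_ids.append(f"vc{i + 1:02d}"); classes.append("non-carrier")
    n_samples = len(sample_ids)
    n_batches = max(1, n_samples // 6)
    # both members of a disease/control pair share a batch, keeping batches
    # class-balanced as in the training design
    batch_of_sample = (np.arange(n_samples) // 2) % n_batches
    sd = config.batch_effect_sd if batch_shift_sd is None else batch_shift_sd
    beta = rng.normal(0.0, sd, size=n_batches)
    disease_mask = np.array([c == "carrier" for c in classes])

    shift = _signal_shift(params, config)
    gene_values = _gene_matrix(params, config, rng, batch_of_sample, beta,
                               disease_mask, np.ones(n_samples), shift)
    exons = _expand_exons(gene_values, params.gene_ids, sample_ids, config, rng)
    meta = _meta_frame(
        sample_ids, classes, [f"val_batch{b + 1}" for b in batch_of_sample],
        np.where(disease_mask, rng.binomial(2, 0.45, n_samples),
                 rng.binomial(2, 0.15, n_samples)),
        ["none"] * n_samples,
    )
    return exons, meta


# ---------------------------------------------------------------------------
# study bundle I/O
# ---------------------------------------------------------------------------

def write_study_bundle(
    out_dir: str | Path,
    exons: ExonMatrix,
    meta: pd.DataFrame,
    sets: GeneSetCollection | None = None,
    truth: GroundTruth | None = None,
) -> dict:
    """Write the standard study bundle (expression TSV, metadata TSV, GMT,
    ground-truth JSON) and return the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    expr = exons.values.copy()
    expr.insert(0, "gene_id", exons.exon_to_gene)
    expr.index.name = "exon_id"
    paths["expression"] = out / "expression.tsv"
    expr.to_csv(paths["expression"], sep="\t")

    paths["meta"] = out / "samples.tsv"
    meta.drop(columns=["sample_id"]).to_csv(paths["meta"], sep="\t",
                                            index_label="sample_id")
    if sets is not None:
        paths["gmt"] = out / "gene_sets.gmt"
        sets.to_gmt(paths["gmt"])
    if truth is not None:
        paths["truth"] = out / "ground_truth.json"
        truth.to_json(paths["truth"])
    return paths
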