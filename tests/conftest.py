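import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from indicell import preprocess
from indicell.features import FeatureTable, GeneSetCollection
from indicell.preprocess import ExpressionMatrix
from indicell.synthdata import SyntheticStudyConfig, generate_cohort


def small_config(**overrides) -> SyntheticStudyConfig:
    """Desk-scale study config used across the unit tests."""
    defaults = dict(
        n_genes=300,
        exons_per_gene=(2, 4),
        n_gene_sets=30,
        set_size_range=(5, 15),
        n_responsive_sets=4,
        effect_size=-0.5,
        noise_sd=0.25,
        n_batches=3,
        n_per_class=10,
        n_outlier_arrays=0,
        seed=7,
    )
    defaults.update(overrides)
    return SyntheticStudyConfig(**defaults)


@pytest.fixture(scope="session")
def small_study():
    """One generated small cohort shared by read-only tests."""
    config = small_config()
    exons, meta, sets, truth = generate_cohort(config)
    return config, exons, meta, sets, truth


@pytest.fixture(scope="session")
def small_ratios(small_study):
    """Marker-normalized log2 ratios of the small cohort."""
    _config, exons, meta, sets, truth = small_study
    m = preprocess.summarize_exons(exons)
    model = preprocess.fit_marker_model(m, meta)
    return preprocess.normalize_log2ratio(m, model=model), meta, sets, truth


def make_feature_table(values: np.ndarray, sample_ids=None, feature_ids=None,
                       kind="gene_ratio") -> FeatureTable:
    values = np.asarray(values, dtype=float)
    sample_ids = sample_ids or [f"s{i}" for i in range(values.shape[0])]
    feature_ids = feature_ids or [f"f{i}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, index=sample_ids, columns=feature_ids)
    return FeatureTable(df, pd.Series(kind, index=df.columns), {})


def make_expression(values: np.ndarray, gene_ids=None, sample_ids=None,
                    scale="log2_ratio") -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids), scale
    )


def make_meta(classes, batches=None, sample_ids=None, apoe4=None) -> pd.DataFrame:
    n = len(classes)
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    meta = pd.DataFrame({
        "sample_id": sample_ids,
        "class": list(classes),
        "batch": batches if batches is not None else ["b1"] * n,
        "apoe4_count": apoe4 if apoe4 is not None else [0] * n,
    }).set_index("sample_id", drop=False)
    return meta
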