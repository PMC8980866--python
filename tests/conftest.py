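"""Shared fixtures: the default synthetic dataset and derived analysis results.

Expensive objects are session-scoped so recovery tests across modules
reuse one simulation (seed 1, the documented fixture seed).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ripeomics import differential, integration
from ripeomics.io_formats import ExpressionMatrix
from ripeomics.synthetic_data import SimulationConfig, SyntheticDataset, generate_dataset

FIXTURE_SEED = 1


def make_matrix(values, sample_stages, kind="counts", feature_ids=None):
    """Small helper to build an ExpressionMatrix from a 2-D array."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    if feature_ids is None:
        feature_ids = [f"g{i}" for i in range(n_feat)]
    sample_ids = [f"s{i}" for i in range(n_samp)]
    reps: dict[str, int] = {}
    rows = []
    for s in sample_stages:
        reps[s] = reps.get(s, 0) + 1
        rows.append((s, reps[s]))
    meta = pd.DataFrame(rows, columns=["stage", "replicate"], index=pd.Index(sample_ids))
    df = pd.DataFrame(values, index=pd.Index(feature_ids, name="feature_id"), columns=sample_ids)
    return ExpressionMatrix(df, meta, kind)


@pytest.fixture(scope="session")
def default_dataset() -> SyntheticDataset:
    return generate_dataset(SimulationConfig(seed=FIXTURE_SEED))


@pytest.fixture(scope="session")
def norm_counts(default_dataset):
    sf = differential.estimate_size_factors(default_dataset.counts)
    return differential.normalize_counts(default_dataset.counts, sf)


@pytest.fixture(scope="session")
def deg_results(default_dataset, norm_counts):
    out = {}
    for b, a in default_dataset.config.contrasts:
        r = differential.test_differential_expression(norm_counts, (a, b))
        out[r.contrast] = r
    return out


@pytest.fixture(scope="session")
def dep_results(default_dataset):
    out = {}
    for b, a in default_dataset.config.contrasts:
        r = differential.test_differential_abundance(default_dataset.proteins, (a, b))
        out[r.contrast] = r
    return out


@pytest.fixture(scope="session")
def paired_with_r(default_dataset):
    paired = integration.pair_omics(
        default_dataset.counts, default_dataset.proteins, default_dataset.id_map
    )
    paired, summary = integration.per_gene_correlation(paired)
    return paired, summary


@pytest.fixture(scope="session")
def null_dataset() -> SyntheticDataset:
    """All-flat simulation: no planted differential signal anywhere."""
    return generate_dataset(
        SimulationConfig(seed=3, template_fractions={"flat": 1.0})
    )
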