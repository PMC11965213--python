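"""Shared fixtures: a seeded default cohort and small hand-built datasets."""

import numpy as np
import pandas as pd
import pytest

from bmecfate.simulate import (
    CohortConfig,
    generate_meta_cohort,
    generate_motif_rankings,
)
from bmecfate.types import ExpressionDataset


def make_dataset(
    values,
    gene_ids=None,
    sample_ids=None,
    unit="raw_counts",
    cell_class="brain_ec",
    vascular_bed="na",
    dataset_id="fixture",
    species="human",
):
    """Small helper to build a valid dataset from a raw array."""
    values = np.asarray(values, dtype=float)
    n_g, n_s = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_g)]
    sample_ids = sample_ids or [f"s{j}" for j in range(n_s)]
    if isinstance(cell_class, str):
        cell_class = [cell_class] * n_s
    if isinstance(vascular_bed, str):
        vascular_bed = [vascular_bed] * n_s
    metadata = pd.DataFrame(
        {"cell_class": cell_class, "vascular_bed": vascular_bed},
        index=sample_ids,
    )
    return ExpressionDataset(
        dataset_id, species, gene_ids, sample_ids, values, unit, metadata
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default meta-cohort, generated once per session (seed 1)."""
    datasets, truth = generate_meta_cohort(CohortConfig(), seed=1)
    return datasets, truth


@pytest.fixture(scope="session")
def default_rankings(default_cohort):
    _, truth = default_cohort
    return generate_motif_rankings(truth, seed=2)
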