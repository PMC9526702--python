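"""Shared fixtures: small synthetic study configurations and trained models."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

import nichedeconv as nd


@pytest.fixture(scope="session")
def small_config() -> nd.SimConfig:
    """A scaled-down study: 400 proteins, 10 patients, all 50 regions."""
    return nd.SimConfig(
        n_proteins=400,
        n_signature_per_niche=30,
        n_patients=10,
        n_regions=None,
        n_bulk=40,
        subtype_counts={
            "proneural": 10,
            "classical": 8,
            "mesenchymal": 12,
            "IDH-mutant": 6,
            "normal": 4,
        },
        seed=1,
    )


@pytest.fixture(scope="session")
def small_atlas(small_config) -> nd.ReferenceAtlas:
    return nd.generate_reference_atlas(small_config)


@pytest.fixture(scope="session")
def small_bulk(small_atlas, small_config) -> nd.BulkCohort:
    return nd.generate_bulk_cohort(small_atlas, small_config)


@pytest.fixture(scope="session")
def processed_pair(small_atlas, small_bulk):
    return nd.preprocess_pair(small_atlas, small_bulk, nd.ImputationParams(seed=7))


@pytest.fixture(scope="session")
def trained_model(processed_pair):
    """Forest trained on a stratified region-level split of the small atlas."""
    atlas_p, _ = processed_pair
    train_ids, test_ids = nd.stratified_split(
        atlas_p.niche_of_sample, 0.8, seed=3,
        region_of_sample=atlas_p.matrix.sample_meta["region"],
    )
    model = nd.train_random_forest(
        nd.ReferenceAtlas(
            matrix=atlas_p.matrix.subset_samples(train_ids),
            niche_of_sample=atlas_p.niche_of_sample.loc[train_ids],
            truth=atlas_p.truth,
        ),
        nd.ForestConfig(n_trees=100, seed=5),
    )
    test_atlas = nd.ReferenceAtlas(
        matrix=atlas_p.matrix.subset_samples(test_ids),
        niche_of_sample=atlas_p.niche_of_sample.loc[test_ids],
        truth=atlas_p.truth,
    )
    return model, test_atlas


def make_matrix(values: np.ndarray, scale_tag: str = "log2",
                groups: list[str] | None = None) -> nd.ProteinMatrix:
    """Wrap a numpy array as a ProteinMatrix with generic ids."""
    n_prot, n_samp = values.shape
    frame = pd.DataFrame(
        values,
        index=[f"G{i:04d}" for i in range(n_prot)],
        columns=[f"S{j:03d}" for j in range(n_samp)],
    )
    meta = pd.DataFrame(index=frame.columns)
    if groups is not None:
        meta["group"] = groups
    return nd.ProteinMatrix(values=frame, sample_meta=meta, scale_tag=scale_tag)
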