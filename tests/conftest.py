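"""Shared fixtures: the study-design synthetic dataset and pipeline run."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from xrfmorph import (
    PipelineConfig,
    build_landmark_matrix,
    default_scenario,
    run_pipeline,
    simulate_dataset,
)

SEED = 1


@pytest.fixture(scope="session")
def scenario():
    return default_scenario(seed=SEED)


@pytest.fixture(scope="session")
def dataset(scenario):
    return simulate_dataset(scenario)


@pytest.fixture(scope="session")
def landmark_matrix(dataset):
    return build_landmark_matrix(dataset.spectra, dataset.manifest)


@pytest.fixture(scope="session")
def pipeline_result(landmark_matrix):
    return run_pipeline(PipelineConfig(seed=SEED), matrix=landmark_matrix, write=False)


@pytest.fixture(scope="session")
def small_scenario():
    """A reduced design (8 specimens, 2 sessions, 1 control) for cheap end-to-end tests."""
    full = default_scenario(seed=7)
    keep_ids = [d.specimen_id for d in full.design
                if d.clade in ("echinoderm", "arthropod")][:8]
    design = tuple(
        dataclasses.replace(d, control=(d.specimen_id == keep_ids[0]))
        for d in full.design
        if d.specimen_id in keep_ids
    )
    return dataclasses.replace(full, design=design, sessions=full.sessions[:2])


@pytest.fixture
def rng():
    return np.random.default_rng(123)
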