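"""Shared fixtures: one synthetic dataset and one full pipeline run per session."""

import numpy as np
import pytest

from lncdev import PipelineConfig, SimulationConfig, generate_dataset
from lncdev.pipeline import run_pipeline


@pytest.fixture(scope="session")
def dataset():
    return generate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def pipeline_state(dataset):
    return run_pipeline(dataset, PipelineConfig(seed=1))


@pytest.fixture(scope="session")
def classified(dataset):
    from lncdev.classify import classify_transcripts

    records = {r.transcript_id: r for r in dataset.focal.records}
    results, models = classify_transcripts(dataset.focal.models, records, dataset.cage)
    return results, models


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
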