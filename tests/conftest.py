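import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import dustlight as dl

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_experiment() -> dl.SyntheticExperiment:
    """One default synthetic experiment shared across the session."""
    return dl.generate_experiment(seed=42)


@pytest.fixture(scope="session")
def default_pipeline(default_experiment) -> dl.pipeline.PipelineResult:
    exp = default_experiment
    return dl.run_pipeline(exp.counts, exp.qpcr, exp.controls, depth=50_000, seed=7)


@pytest.fixture(scope="session")
def community_treatments(default_experiment) -> pd.Series:
    meta = default_experiment.counts.metadata
    return meta.drop_duplicates("community").set_index("community")["treatment"]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def small_count_table(counts: dict, metadata: dict | None = None) -> dl.CountTable:
    """Helper: build a CountTable from {sample: {taxon: count}} dicts."""
    df = pd.DataFrame(counts).T.fillna(0).astype(np.int64)
    df.index.name = "sample"
    meta = None
    if metadata is not None:
        meta = pd.DataFrame(metadata).T
        meta.index.name = "sample"
    return dl.CountTable(df, meta)
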