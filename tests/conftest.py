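import numpy as np
import pytest

from peachem import (
    PipelineConfig,
    build_default_spec,
    run_pipeline,
    sample_composition,
)


@pytest.fixture(scope="session")
def default_spec():
    return build_default_spec()


@pytest.fixture(scope="session")
def comp2000(default_spec):
    """Large seeded composition draw shared by statistical tests."""
    return sample_composition(default_spec, 2000, seed=123)


@pytest.fixture(scope="session")
def pipeline_report():
    """One default 90-sample pipeline run shared by slow tests."""
    return run_pipeline(PipelineConfig(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
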