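import numpy as np
import pytest

from ctermx import CohortConfig, PipelineConfig, load_table1_fixture, run_pipeline, simulate_cohort
from ctermx.simulate import downstream_annotations


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20150521)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort exercising every event kind at least once."""
    cfg = CohortConfig(additions=4, subtractions=2, singletons=3, double_singletons=1,
                       fusions=1, polyN=2, clean=7, n_focal=10, n_sister=8, orf_codons=80)
    families, truth = simulate_cohort(cfg, 7)
    return cfg, families, truth, downstream_annotations()


@pytest.fixture(scope="session")
def small_cohort_result(small_cohort):
    _, families, _, downstream = small_cohort
    config = PipelineConfig(downstream_starts=downstream)
    return config, run_pipeline(families, config)
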