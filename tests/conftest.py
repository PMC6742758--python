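import numpy as np
import pytest

from viromeco import simgen
from viromeco.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def small_panel():
    return simgen.generate_panel(60, (1500, 3000), seed=101)


@pytest.fixture(scope="session")
def tiny_config():
    """Small but complete pipeline configuration for fast end-to-end tests."""
    return PipelineConfig(
        seed=5,
        n_viruses=80,
        genome_length_min=1200,
        genome_length_max=2500,
        samples_per_type=2,
        n_viruses_high=10,
        n_viruses_low=4,
        reads_per_virus=30,
        n_permutations=199,
        permtest_iterations=300,
        contigs_per_draw=50,
        rarefaction_fractions=(0.5, 1.0),
        rarefaction_replicates=3,
    )


@pytest.fixture(scope="session")
def tiny_run(tiny_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("tiny_run")
    manifest = run_pipeline(tiny_config, out)
    return out, manifest


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full default-scale study run (the two-cluster design), shared
    by the acceptance-level checks."""
    out = tmp_path_factory.mktemp("default_run")
    manifest = run_pipeline(PipelineConfig(seed=11), out)
    return out, manifest
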