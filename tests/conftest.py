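import numpy as np
import pytest

from secircuit import CohortConfig, PipelineConfig, generate_cohort
from secircuit.pipeline import run as pipeline_run

# n_crc_tfs must not exceed ceil(0.15 * n_tfs) or the planted CRC TFs
# cannot all fit in the master set
SMALL = dict(n_se=60, n_genes=250, n_tfs=20, n_crc_tfs=3, n_ctp_triples=10, seed=5)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A reduced synthetic cohort bundle shared across tests."""
    out = tmp_path_factory.mktemp("cohort")
    path, truth = generate_cohort(CohortConfig(**SMALL), out / "bundle")
    return path, truth


@pytest.fixture(scope="session")
def small_run(tmp_path_factory, small_cohort):
    """A completed pipeline run on the reduced cohort."""
    bundle, truth = small_cohort
    run_dir = tmp_path_factory.mktemp("run") / "out"
    cfg = PipelineConfig.from_bundle(bundle, seed=5, n_perm=300, ci_n_perm=200)
    pipeline_run(cfg, run_dir)
    return run_dir, bundle, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
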