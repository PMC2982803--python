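import numpy as np
import pytest

from phylosym.pipeline import PipelineConfig, run_pipeline
from phylosym.simulate import default_host_spec


@pytest.fixture(scope="session")
def strong_run():
    """The full strong-signal study condition: 10 samples, 5 species, 200
    planted OTUs, 5,000 reads/sample, 200 bootstrap pseudo-replicates."""
    return run_pipeline(PipelineConfig(), seed=1)


@pytest.fixture(scope="session")
def small_run():
    """A reduced end-to-end experiment shared across tests: strong signal,
    60 planted OTUs, 800 reads/sample, light bootstrap."""
    cfg = PipelineConfig(n_otus=60, depth=800, bootstrap_reps=60, n_starts=5)
    return run_pipeline(cfg, seed=7)


@pytest.fixture(scope="session")
def fidelity_run():
    """Substitution-only error model, where every read's filter outcome is
    exactly determined by the planted attributes."""
    cfg = PipelineConfig(n_otus=60, depth=1200, error_rates=(0.002, 0.0, 0.0),
                         bootstrap_reps=0, n_starts=3)
    return run_pipeline(cfg, seed=11)


@pytest.fixture(scope="session")
def replicate_run():
    """A run carrying a technical-replicate pair (Homo_1 resequenced 3.5x)."""
    cfg = PipelineConfig(n_otus=50, depth=600, bootstrap_reps=0, n_starts=3,
                         replicate_of="Homo_1")
    return run_pipeline(cfg, seed=13)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
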