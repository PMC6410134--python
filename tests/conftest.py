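import numpy as np
import pytest

from ervsegmap.config import AlleleFrequencyModel, RunConfig, SimulationConfig
from ervsegmap.pipeline import run_all


PRIVATE_SHARED_CYCLE = (
    (1.0, 0.0, 0.0),
    (0.0, 1.0, 0.0),
    (0.0, 0.0, 1.0),
    (1.0, 1.0, 1.0),
)


@pytest.fixture(scope="session")
def mixed_run(tmp_path_factory):
    """End-to-end run on 200 noise-free insertions cycling through
    H-private, L-private, W-private and shared (each line carries its own
    private loci, as in real pools): the parameter-recovery workhorse."""
    cfg = RunConfig(
        simulation=SimulationConfig(
            seed=7,
            n_insertions=200,
            noise_rate=0.0,
            solo_ltr_fraction=0.0,
            allele_freq_model=AlleleFrequencyModel(
                kind="cycle", freq_list=PRIVATE_SHARED_CYCLE
            ),
        )
    )
    outdir = tmp_path_factory.mktemp("mixed_run")
    manifest = run_all(cfg, outdir)
    return cfg, outdir, manifest


@pytest.fixture
def rng():
    return np.random.default_rng(20_240)
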