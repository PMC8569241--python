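import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from fusionforge.pipeline import run_pipeline
from fusionforge.simulate import (SimConfig, default_fusion_set, make_panel,
                                  simulate_reads)


@pytest.fixture(scope="session")
def panel():
    return make_panel(6, seed=3)


@pytest.fixture(scope="session")
def truths(panel):
    return default_fusion_set(panel, 4, seed=3, n_molecules=20)


@pytest.fixture(scope="session")
def sim(panel, truths):
    cfg = SimConfig(seed=11, n_background_molecules=60)
    r1, r2, molecules = simulate_reads(panel, truths, cfg)
    return {"r1": r1, "r2": r2, "molecules": molecules, "config": cfg}


@pytest.fixture(scope="session")
def e2e(panel, truths, sim):
    """One shared end-to-end pipeline run on the small positive sample."""
    return run_pipeline(sim["r1"], sim["r2"], panel.genome, panel.transcripts)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
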