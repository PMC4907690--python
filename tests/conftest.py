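import numpy as np
import pytest

import painsig as ps


@pytest.fixture(scope="session")
def small_sim():
    """Desk-scale synthetic study used by fast structural tests."""
    return ps.simulate_dataset(grid_shape=(10, 12, 10), n_subjects=8, seed=7)


@pytest.fixture(scope="session")
def study1():
    """Full-size strong-signal study (the standard validation conditions)."""
    return ps.simulate_dataset(seed=1)


@pytest.fixture(scope="session")
def study42():
    """Full-size strong-signal study used by the recovery checks."""
    return ps.simulate_dataset(seed=42)


@pytest.fixture(scope="session")
def cv1(study1):
    """LOSO LASSO-PCR cross-validation per modality on the seed-1 study."""
    cfg = ps.TrainerConfig(seed=0)
    return {m: ps.loso_crossval(study1.dataset, m, cfg)
            for m in ("somatic", "vicarious")}


@pytest.fixture(scope="session")
def cv42_somatic(study42):
    return ps.loso_crossval(study42.dataset, "somatic", ps.TrainerConfig(seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
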