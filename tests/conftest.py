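import numpy as np
import pytest

from episcope.simulate import SynthConfig, generate


@pytest.fixture(scope="session")
def small_sim():
    """A desk-size cohort with planted structure for fast module tests."""
    cfg = SynthConfig(n_probes=400, n_prognostic=8, n_responsive=40, seed=11)
    return generate(cfg)


@pytest.fixture(scope="session")
def default_sim():
    """One cohort at the default study conditions (34 patients, 5000 probes)."""
    return generate(SynthConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)
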