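import numpy as np
import pytest

from hippoephys import synthio


@pytest.fixture(scope="session")
def clean_lfp():
    """60 s of pure 1/f (exponent 1) LFP at 2 kHz, no oscillations."""
    ts, gt = synthio.gen_lfp(synthio.LfpSpec(
        duration_s=60.0, rate_hz=2000.0, aperiodic_offset=-1.0,
        aperiodic_exponent=1.0, seed=101))
    return ts


@pytest.fixture(scope="session")
def theta_lfp():
    """LFP carrying a strong narrowband 8 Hz oscillation on 1/f background."""
    ts, gt = synthio.gen_lfp(synthio.LfpSpec(
        duration_s=60.0, rate_hz=2000.0, aperiodic_offset=-1.0,
        aperiodic_exponent=1.0, oscillations=[(8.0, 1.0, 0.5)], seed=102))
    return ts


@pytest.fixture(scope="session")
def psc_sweep_default():
    """Default EPSC sweep (30 s, 20 kHz, 5 Hz events) with ground truth."""
    spec = synthio.PscSweepSpec(seed=103)
    return synthio.gen_psc_sweep(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
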