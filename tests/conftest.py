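import numpy as np
import pytest

from spikelfp import LfpTrace, SpikeTrain
from spikelfp import synthdata as sd


@pytest.fixture(scope="session")
def control_session():
    """One 240 s control-template session with ground truth (shared)."""
    cfg = sd.control_template(seed=11, duration_s=240.0)
    bundle, truth = sd.gen_session(cfg)
    return cfg, bundle, truth


@pytest.fixture()
def cosine_lfp():
    """10 s of a pure 20 Hz cosine at 1 kHz."""
    t = np.arange(10_000) / 1000.0
    return LfpTrace(np.cos(2 * np.pi * 20.0 * t), 1000.0)


def poisson_train(rate, duration, seed, unit_id="u"):
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate * duration)
    times = np.unique(rng.uniform(0.0, duration, n))
    return SpikeTrain(unit_id, times, 0.0, duration)
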