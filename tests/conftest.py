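import numpy as np
import pytest

from pupilbands.core import SampledSignal
from pupilbands.synthetic import SyntheticRunConfig, synthesize_pupil, synthesize_rr


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_run_cfg():
    """A single fast run: 400 s, modest pupil rate."""
    return SyntheticRunConfig(duration=400.0, pupil_fs=60.0, seed=11)


@pytest.fixture(scope="session")
def short_run(short_run_cfg):
    return synthesize_rr(short_run_cfg), synthesize_pupil(short_run_cfg)


def make_signal(values, fs=8.0, t0=0.0, mask=None):
    return SampledSignal(np.asarray(values, dtype=float), fs, t0, mask)
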