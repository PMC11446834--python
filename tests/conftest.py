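import numpy as np
import pytest

from eflkit.config import RunConfig
from eflkit.pipeline import analyze_study
from eflkit.signal_io import FlowVolumeSignal
from eflkit.synthetic import StudyConfig, gen_two_visit_study

FS = 200.0


def make_sine_session(
    n_breaths: int = 8,
    period: float = 4.0,
    amp: float = 1.0,
    fs: float = FS,
    drift: float = 0.0,
    noise: float = 0.0,
    seed: int = 0,
    amp_per_breath=None,
) -> FlowVolumeSignal:
    """Sinusoidal breathing: flow = -amp·sin(2πt/period) (inspiration first).

    One period is one breath; tidal volume = amp·period/π.  Optional
    linear volume drift and Gaussian flow noise; ``amp_per_breath``
    modulates amplitude breath by breath.
    """
    t = np.arange(int(n_breaths * period * fs)) / fs
    if amp_per_breath is None:
        flow = -amp * np.sin(2 * np.pi * t / period)
    else:
        amps = np.asarray(amp_per_breath, float)[
            np.minimum((t / period).astype(int), len(amp_per_breath) - 1)
        ]
        flow = -amps * np.sin(2 * np.pi * t / period)
    rng = np.random.default_rng(seed)
    if noise:
        flow = flow + rng.normal(0, noise, t.size)
    # volume from the clean integral so ground truth stays exact
    vol = np.concatenate(
        [[0.0], np.cumsum(-(flow[1:] + flow[:-1]) / (2 * fs))]
    )
    vol = vol + drift * t
    return FlowVolumeSignal(time=t, flow=flow, volume=vol, fs=fs)


@pytest.fixture(scope="session")
def small_study():
    """A 6-participant two-visit synthetic study (fixed seed)."""
    return gen_two_visit_study(StudyConfig(n_participants=6, seed=11))


@pytest.fixture(scope="session")
def small_study_results(small_study):
    return analyze_study(small_study, RunConfig())
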