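import numpy as np
import pytest

from cowgait import Config, detect_trial_events, regularity_screen, segment_strides

from cowgait.simulate import (
    GaitParams,
    NoiseParams,
    UpperBodyParams,
    simulate_limb_streams,
    simulate_trial,
)


@pytest.fixture(scope="session")
def config():
    return Config()


@pytest.fixture(scope="session")
def clean_limb_sim():
    """Noise-free, jitter-free limb streams with ground truth."""
    gait = GaitParams(n_strides=10, timing_jitter_sd=0.0)
    streams, truth = simulate_limb_streams(gait, NoiseParams(0.0, 0.0, seed=1))
    return gait, streams, truth


@pytest.fixture(scope="session")
def noisy_limb_sim():
    """Default-noise, jittered limb streams with ground truth."""
    gait = GaitParams(n_strides=12, timing_jitter_sd=0.015)
    streams, truth = simulate_limb_streams(
        gait, NoiseParams(0.5, 2.0, seed=3), rng=np.random.default_rng(3)
    )
    return gait, streams, truth


@pytest.fixture(scope="session")
def clean_trial():
    """Noise-free full-trial simulation with events and screened strides."""
    trial, truth = simulate_trial(
        GaitParams(n_strides=10, timing_jitter_sd=0.0),
        UpperBodyParams(),
        NoiseParams(0.0, 0.0, seed=5),
    )
    cfg = Config()
    events = detect_trial_events(trial, cfg)
    strides = regularity_screen(segment_strides(events), events, cfg)
    return trial, truth, events, strides


@pytest.fixture(scope="session")
def noisy_trial():
    trial, truth = simulate_trial(
        GaitParams(n_strides=15, timing_jitter_sd=0.01),
        UpperBodyParams(),
        NoiseParams(0.3, 1.0, seed=6),
    )
    cfg = Config()
    events = detect_trial_events(trial, cfg)
    strides = regularity_screen(segment_strides(events), events, cfg)
    return trial, truth, events, strides


def match_errors(detected, truth):
    """Max distance from each detected event to its nearest true event (s)."""
    detected = np.asarray(detected)
    truth = np.asarray(truth)
    if detected.size == 0:
        return 0.0
    return np.abs(detected[:, None] - truth[None, :]).min(axis=1).max()
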