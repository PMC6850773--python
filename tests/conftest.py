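import numpy as np
import pytest

from novelsupp import SimConfig, simulate_behavior, simulate_traces
from novelsupp.behavior import BehaviorSession


@pytest.fixture(scope="session")
def short_cfg():
    return SimConfig(epoch_durations=(60.0, 120.0, 60.0), n_cells=6, seed=11)


@pytest.fixture(scope="session")
def short_session(short_cfg):
    behavior = simulate_behavior(short_cfg)
    raw, neuropil, truth, fb = simulate_traces(behavior, short_cfg)
    return {
        "behavior": behavior,
        "raw": raw,
        "neuropil": neuropil,
        "truth": truth,
        "fb": fb,
        "config": short_cfg,
    }


def constant_speed_session(
    epoch_durations=(60.0, 120.0, 60.0), speed=20.0, rate=100.0, track_length=180.0
) -> BehaviorSession:
    """Hand-built session with perfectly constant locomotion (no generator
    randomness), for exact-ratio checks."""
    n_per = [int(d * rate) for d in epoch_durations]
    n = sum(n_per)
    t = np.arange(n) / rate
    # bounce between track ends at constant speed
    period = 2 * track_length / speed
    phase = (t % period) / period
    pos = np.where(phase < 0.5, 2 * track_length * phase, 2 * track_length * (1 - phase))
    return BehaviorSession(
        t=t,
        position=pos,
        forward_speed=np.full(n, speed),
        rot_speed=np.zeros(n),
        vr_speed=np.full(n, speed),
        lick=np.zeros(n, np.uint8),
        reward_times=np.empty(0),
        epoch=np.repeat(np.arange(3), n_per),
        epoch_names=("Fam", "New", "FamPrime"),
        rate=rate,
        track_length=track_length,
    )


@pytest.fixture
def const_behavior():
    return constant_speed_session()
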