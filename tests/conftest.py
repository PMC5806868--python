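import numpy as np
import pytest

import meakit as mk

FS = 20_000.0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_recording(rng):
    """4-channel, 1000-sample Gaussian-noise recording at 20 kHz."""
    return mk.AnalogRecording(
        channel_ids=["A1", "B1", "A2", "B2"],
        data=rng.normal(0, 10, (4, 1000)),
        sampling_rate=FS,
    )


@pytest.fixture
def sorting_scene():
    """Two-template sorting preset with its ground truth."""
    cfg = mk.preset_config("two-template-sorting", seed=7)
    rec, truth = mk.generate(cfg)
    return rec, truth


def match_events(true_times, found_times, tol_s):
    """One-to-one greedy matching; returns number of matched true events."""
    true_times = np.sort(np.asarray(true_times))
    found_times = np.sort(np.asarray(found_times))
    i = j = hits = 0
    while i < true_times.size and j < found_times.size:
        dt = found_times[j] - true_times[i]
        if abs(dt) <= tol_s:
            hits += 1
            i += 1
            j += 1
        elif dt < 0:
            j += 1
        else:
            i += 1
    return hits
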