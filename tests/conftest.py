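import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def quiet_trace_cfg():
    """Zero-noise generator configuration for exact-recovery tests."""
    from dendrocalc import TraceGenConfig

    return TraceGenConfig(noise_sd=0.0, f_rest_jitter=0.0, seed=11)


@pytest.fixture
def small_trace_set(quiet_trace_cfg):
    from dendrocalc import generate_trace_set

    return generate_trace_set(quiet_trace_cfg, n_somas=1, n_dendrites=2, n_spines_per_dendrite=3)


def naive_event_scan(dff, thr_per_sample, trial_index):
    """Independent per-sample reference detector: walks the trace once and
    closes an event on any sub-threshold sample or trial change."""
    events = []
    start = None
    for i, (x, t) in enumerate(zip(dff, thr_per_sample)):
        boundary = i > 0 and trial_index[i] != trial_index[i - 1]
        if start is not None and boundary:
            events.append((start, i - 1))
            start = None
        if x >= t:
            if start is None:
                start = i
        else:
            if start is not None:
                events.append((start, i - 1))
                start = None
    if start is not None:
        events.append((start, len(dff) - 1))
    return events
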