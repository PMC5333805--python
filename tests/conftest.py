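import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import twitchva as tv

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def protocol():
    return tv.ProtocolSpec()


@pytest.fixture
def fast_protocol():
    """Short trials for structural/counting tests (timing-valid, cheap)."""
    return tv.ProtocolSpec(
        rest_stimulus_delay=1.5,
        trial_duration=3.5,
        stim1_time=1.3,
        mvc_plateau_duration=1.0,
    )


@pytest.fixture
def noiseless_gt():
    return tv.ArmGroundTruth(
        "arm1", "biceps", "horizontal", full_activation_moment=10.0,
        true_va=0.7, noise_sd=0.0,
    )


@pytest.fixture
def make_condition(protocol):
    """Simulate all trials for one arm x posture with given overrides."""

    def _make(seed=0, **gt_kwargs):
        defaults = dict(
            arm_id="arm1", transfer_group="biceps", posture="horizontal",
            full_activation_moment=10.0, true_va=0.7,
        )
        defaults.update(gt_kwargs)
        gt = tv.ArmGroundTruth(**defaults)
        return tv.simulate_condition(gt, protocol, seed=seed), gt

    return _make


@pytest.fixture
def constant_trace():
    def _make(value=3.0, duration=2.0, fs=1000.0, units="newton_meters"):
        n = int(round(duration * fs))
        return tv.MomentTrace(np.full(n, float(value)), fs, units)

    return _make
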