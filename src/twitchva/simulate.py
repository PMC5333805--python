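"""Synthetic interpolated-twitch experiments with known ground truth.

The generator produces complete studies — per-trial moment traces, a
trial manifest, and a ground-truth table — that obey the linear
twitch-occlusion model the interpolated-twitch technique assumes: the
amplitude of the moment increment evoked by a supramaximal stimulus
falls linearly with voluntary drive,

    T(v) = T0 * (1 - v),        v = effort * true_va,

where ``T0`` is the resting twitch and ``v`` the fraction of the motor
pool recruited voluntarily.  With that model the (voluntary moment,
twitch amplitude) pairs lie exactly on a line whose x-intercept is the
full-activation moment, so the downstream pipeline can be validated by
parameter recovery.

Protocol emulated (per arm x posture): three 5-s maximum voluntary
trials, then six moment-matching trials at each of 33%, 66% and 100% of
maximum.  Each matched trial carries one stimulus superimposed on the
held effort (delivered after the target has been held within +/-5% for
250 ms) and one resting stimulus 7 s later.  Stimulation hardware
(electrode placement, intensity search) is out of scope: the stimulus
is assumed supramaximal and constant, and posture enters only as a
categorical label whose ground-truth parameters the caller supplies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParameterError, ValidationError
from .signal import NEWTON_METERS, MomentTrace
from .twitch import MATCHED, MVC, TrialRecord

TRANSFER_GROUPS = ("biceps", "deltoid")
POSTURES = ("horizontal", "overhead_reach", "pressure_relief")

_SEED_MASK = 0x7FFFFFFF  # derived seeds kept below 2**31


@dataclass
class ArmGroundTruth:
    """True parameters of one arm in one posture.

    ``full_activation_moment`` is the moment the arm would generate if
    the entire motor pool of the transferred muscle were recruited;
    ``true_va`` the fraction recruited at maximum voluntary effort, so
    the implied maximum voluntary moment is ``true_va *
    full_activation_moment``.  ``rest_twitch_amplitude`` defaults to
    20% of the full-activation moment, in the range reported for
    supramaximal single twitches.  ``occlusion_curvature`` (default 0)
    bends the twitch-vs-drive relation for robustness studies;
    ``drift_rate`` (default 0, N·m/s) adds a linear plateau drift.
    """

    arm_id: str
    transfer_group: str
    posture: str
    full_activation_moment: float  # N·m
    true_va: float  # (0, 1.1]
    rest_twitch_amplitude: float | None = None  # N·m; default 0.2 * M_full
    twitch_time_constant: float = 0.07  # s; peak inside the 150-ms window
    noise_sd: float | None = None  # N·m; default 2% of M_full
    tremor_amplitude: float = 0.0  # N·m
    tremor_frequency: float = 8.0  # Hz
    occlusion_curvature: float = 0.0
    drift_rate: float = 0.0  # N·m/s during held efforts
    subject_id: str | None = None

    def __post_init__(self):
        if self.transfer_group not in TRANSFER_GROUPS:
            raise ValidationError(
                f"transfer_group {self.transfer_group!r} not in {TRANSFER_GROUPS}"
            )
        if self.posture not in POSTURES:
            raise ValidationError(f"posture {self.posture!r} not in {POSTURES}")
        if not self.full_activation_moment > 0:
            raise ParameterError("full_activation_moment must be > 0")
        if not 0 < self.true_va <= 1.1:
            raise ParameterError("true_va must lie in (0, 1.1]")
        if self.rest_twitch_amplitude is None:
            self.rest_twitch_amplitude = 0.2 * self.full_activation_moment
        if not self.rest_twitch_amplitude > 0:
            raise ParameterError("rest_twitch_amplitude must be > 0")
        if not self.twitch_time_constant > 0:
            raise ParameterError("twitch_time_constant must be > 0")
        if self.noise_sd is None:
            self.noise_sd = 0.02 * self.full_activation_moment
        if self.noise_sd < 0 or self.tremor_amplitude < 0:
            raise ParameterError("noise_sd and tremor_amplitude must be >= 0")
        if self.subject_id is None:
            self.subject_id = self.arm_id

    @property
    def max_voluntary_moment(self) -> float:
        return self.true_va * self.full_activation_moment


@dataclass(frozen=True)
class ProtocolSpec:
    """Timing and structure of the stimulation protocol."""

    sampling_rate: float = 1000.0  # Hz
    n_mvc_trials: int = 3
    target_levels: tuple[float, ...] = (0.33, 0.66, 1.0)
    trials_per_level: int = 6
    hold_tolerance: float = 0.05  # fraction of target
    hold_duration: float = 0.25  # s within tolerance before stimulus
    rest_stimulus_delay: float = 7.0  # s between the two stimuli
    trial_duration: float = 10.0  # s, matched trials
    mvc_plateau_duration: float = 5.0  # s of held maximum effort
    stim1_time: float = 2.0  # s, first (superimposed) stimulus
    ramp_duration: float = 0.5  # s, effort onset/offset ramps
    rest_before: float = 0.5  # s of rest at trial start
    post_stimulus_hold: float = 0.5  # s the effort is held past the stimulus

    def __post_init__(self):
        levels = tuple(self.target_levels)
        if not levels or any(not 0 < x <= 1 for x in levels):
            raise ConfigurationError("target levels must lie in (0, 1]")
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ConfigurationError("target levels must be strictly increasing")
        if not self.rest_stimulus_delay > self.hold_duration:
            raise ConfigurationError("rest_stimulus_delay must exceed hold_duration")
        if self.rest_stimulus_delay < self.post_stimulus_hold + self.ramp_duration + 0.25:
            raise ConfigurationError(
                "rest_stimulus_delay too short: the arm must be fully relaxed "
                "for at least 250 ms before the resting stimulus"
            )
        if self.stim1_time < self.rest_before + self.ramp_duration + self.hold_duration:
            raise ConfigurationError(
                "stim1_time leaves no room for the ramp and the 250-ms hold"
            )

    @property
    def stim2_time(self) -> float:
        return self.stim1_time + self.rest_stimulus_delay

    @property
    def trials_per_condition(self) -> int:
        return self.n_mvc_trials + self.trials_per_level * len(self.target_levels)

    @property
    def mvc_duration(self) -> float:
        return 2 * (self.rest_before + self.ramp_duration) + self.mvc_plateau_duration


@dataclass
class StudyDataset:
    """Simulated study: trials plus manifest and ground-truth tables."""

    trials: list[TrialRecord]
    manifest: pd.DataFrame
    ground_truth: pd.DataFrame


def twitch_waveform(
    t: np.ndarray | float, amplitude: float, time_constant: float
) -> np.ndarray | float:
    """Impulse-response shape of the evoked twitch.

    ``amplitude * (t/tau) * exp(1 - t/tau)``: zero at onset, unimodal,
    peaking at ``t = tau`` with peak value exactly ``amplitude``; zero
    for ``t < 0``.
    """
    if not time_constant > 0:
        raise ParameterError("time_constant must be positive")
    t = np.asarray(t, dtype=float)
    x = np.clip(t / time_constant, 0.0, None)
    out = amplitude * x * np.exp(1.0 - x)
    return out if out.ndim else float(out)


def _raised_cosine(x: np.ndarray) -> np.ndarray:
    return np.where(x <= 0, 0.0, np.where(x >= 1, 1.0, 0.5 - 0.5 * np.cos(np.pi * np.clip(x, 0, 1))))


def _effort_envelope(
    t: np.ndarray, onset: float, ramp: float, plateau_end: float
) -> np.ndarray:
    """0→1 ramp at ``onset``, hold, 1→0 ramp starting at ``plateau_end``.

    Ramps are raised-cosine: effort onset/offset is smooth, as real
    subjects' is, and the smoothness keeps the low-pass filter from
    ringing at the plateau corners.
    """
    up = _raised_cosine((t - onset) / ramp)
    down = 1.0 - _raised_cosine((t - plateau_end) / ramp)
    return np.minimum(up, down)


def simulate_trial(
    gt: ArmGroundTruth,
    protocol: ProtocolSpec,
    target_level: float | None,
    trial_type: str,
    seed: int,
    trial_id: str | None = None,
) -> TrialRecord:
    """Simulate one trial; identical seeds yield bit-identical traces.

    Matched trials: the plateau is held at ``target * (1 + jitter)``
    with jitter uniform within the +/-5% hold tolerance (subjects only
    hold within tolerance), capped so the achieved effort never exceeds
    1 — a subject cannot out-drive their own maximum.  The superimposed
    twitch amplitude follows the occlusion model at the *achieved*
    drive; the resting twitch has the full resting amplitude on a
    relaxed ~0 N·m baseline.  Maximum-effort trials hold a 5-s plateau
    at ``true_va * full_activation_moment`` and carry no stimuli.
    """
    rng = np.random.default_rng(seed)
    fs = protocol.sampling_rate

    if trial_type == MVC:
        duration = protocol.mvc_duration
        effort = 1.0
        stim_times: tuple[float, ...] = ()
        plateau_end = protocol.rest_before + protocol.ramp_duration + protocol.mvc_plateau_duration
    elif trial_type == MATCHED:
        if target_level is None or not any(
            np.isclose(target_level, lv) for lv in protocol.target_levels
        ):
            raise ConfigurationError(
                f"target_level {target_level} not in protocol levels "
                f"{protocol.target_levels}"
            )
        duration = protocol.trial_duration
        if protocol.stim2_time + 0.5 > duration:
            raise ConfigurationError(
                "trial too short to contain both stimuli plus the analysis window"
            )
        if np.isclose(target_level, 1.0):
            # a maximal target is not "matched": the subject simply pushes
            # as hard as they can, so the achieved effort is their maximum
            effort = 1.0
        else:
            jitter = rng.uniform(-protocol.hold_tolerance, protocol.hold_tolerance)
            effort = target_level * (1.0 + jitter)
        stim_times = (protocol.stim1_time, protocol.stim2_time)
        plateau_end = protocol.stim1_time + protocol.post_stimulus_hold
    else:
        raise ValidationError(f"unknown trial_type {trial_type!r}")

    n = int(round(duration * fs))
    t = np.arange(n) / fs
    env = _effort_envelope(t, protocol.rest_before, protocol.ramp_duration, plateau_end)

    drive = effort * gt.true_va
    moment = env * drive * gt.full_activation_moment
    if gt.drift_rate:
        moment += env * gt.drift_rate * np.clip(
            t - (protocol.rest_before + protocol.ramp_duration), 0.0, None
        )

    if trial_type == MATCHED:
        occ = (1.0 - drive) + gt.occlusion_curvature * drive * (1.0 - drive)
        moment += twitch_waveform(
            t - protocol.stim1_time, gt.rest_twitch_amplitude * occ, gt.twitch_time_constant
        )
        moment += twitch_waveform(
            t - protocol.stim2_time, gt.rest_twitch_amplitude, gt.twitch_time_constant
        )

    if gt.tremor_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        moment += env * gt.tremor_amplitude * np.sin(
            2 * np.pi * gt.tremor_frequency * t + phase
        )
    if gt.noise_sd > 0:
        moment += rng.normal(0.0, gt.noise_sd, n)

    if trial_id is None:
        trial_id = f"{gt.arm_id}_{gt.posture}_{trial_type}"
    return TrialRecord(
        trial_id=trial_id,
        arm_id=gt.arm_id,
        transfer_group=gt.transfer_group,
        posture=gt.posture,
        trial_type=trial_type,
        target_level=target_level,
        trace=MomentTrace(moment, fs, NEWTON_METERS),
        stim_times=stim_times,
        subject_id=gt.subject_id,
    )


def simulate_condition(
    gt: ArmGroundTruth, protocol: ProtocolSpec, seed: int
) -> list[TrialRecord]:
    """All trials for one arm x posture: MVCs then matched blocks."""
    child_seeds = np.random.SeedSequence(seed).generate_state(
        protocol.trials_per_condition
    ) & _SEED_MASK
    trials = []
    k = 0
    for i in range(protocol.n_mvc_trials):
        trials.append(
            simulate_trial(
                gt, protocol, None, MVC, int(child_seeds[k]),
                trial_id=f"{gt.arm_id}_{gt.posture}_mvc{i + 1}",
            )
        )
        k += 1
    for level in protocol.target_levels:
        for i in range(protocol.trials_per_level):
            trials.append(
                simulate_trial(
                    gt, protocol, level, MATCHED, int(child_seeds[k]),
                    trial_id=f"{gt.arm_id}_{gt.posture}_m{int(round(level * 100))}_{i + 1}",
                )
            )
            k += 1
    return trials


def simulate_study(
    ground_truths: list[ArmGroundTruth], protocol: ProtocolSpec, seed: int
) -> StudyDataset:
    """Simulate a full study, one trial block per arm x posture entry."""
    pairs = [(gt.arm_id, gt.posture) for gt in ground_truths]
    if len(set(pairs)) != len(pairs):
        dup = [p for p in pairs if pairs.count(p) > 1][0]
        raise ValidationError(f"duplicate arm x posture ground truth: {dup}")

    cond_seeds = np.random.SeedSequence(seed).generate_state(
        max(len(ground_truths), 1)
    ) & _SEED_MASK
    trials: list[TrialRecord] = []
    manifest_rows = []
    gt_rows = []
    for gt, cseed in zip(ground_truths, cond_seeds):
        block = simulate_condition(gt, protocol, int(cseed))
        trials.extend(block)
        for tr in block:
            manifest_rows.append(
                {
                    "trial_id": tr.trial_id,
                    "arm_id": tr.arm_id,
                    "subject_id": tr.subject_id,
                    "transfer_group": tr.transfer_group,
                    "posture": tr.posture,
                    "trial_type": tr.trial_type,
                    "target_level": tr.target_level,
                    "stim1_time_s": tr.stim_times[0] if tr.stim_times else None,
                    "stim2_time_s": tr.stim_times[1] if tr.stim_times else None,
                    "trace_path": f"traces/{tr.trial_id}.csv",
                }
            )
        gt_rows.append(
            {
                "arm_id": gt.arm_id,
                "subject_id": gt.subject_id,
                "transfer_group": gt.transfer_group,
                "posture": gt.posture,
                "full_activation_moment": gt.full_activation_moment,
                "true_va": gt.true_va,
                "max_voluntary_moment": gt.max_voluntary_moment,
                "rest_twitch_amplitude": gt.rest_twitch_amplitude,
                "noise_sd": gt.noise_sd,
            }
        )

    manifest_cols = [
        "trial_id", "arm_id", "subject_id", "transfer_group", "posture",
        "trial_type", "target_level", "stim1_time_s", "stim2_time_s", "trace_path",
    ]
    gt_cols = [
        "arm_id", "subject_id", "transfer_group", "posture",
        "full_activation_moment", "true_va", "max_voluntary_moment",
        "rest_twitch_amplitude", "noise_sd",
    ]
    return StudyDataset(
        trials=trials,
        manifest=pd.DataFrame(manifest_rows, columns=manifest_cols),
        ground_truth=pd.DataFrame(gt_rows, columns=gt_cols),
    )
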