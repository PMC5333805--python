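"""Per-trial reduction: voluntary effort and stimulus-evoked twitch.

Each moment-matching trial carries two electrical stimulus events: one
superimposed on the held voluntary contraction and one ~7 s later with
the arm relaxed (the 0%-effort response).  Every stimulus event is
reduced to two numbers:

* pre-stimulus moment — mean moment over the 250 ms preceding the
  stimulus (half-open window, stimulus sample excluded);
* twitch amplitude — maximum moment within 150 ms after the stimulus
  (closed window) minus the pre-stimulus moment.  Negative amplitudes
  are retained: near full activation the evoked increment can vanish
  into the noise and they are legitimate regression inputs.

Maximum voluntary moment is the greatest 0.5-s sustained mean over the
dedicated maximum-effort trials, optionally pooled with the pre-stimulus
portion of 100%-target matched trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import BoundsError, MissingDataError, QCWarning, ValidationError
from .signal import MomentTrace, max_sustained_mean, window_mean

MVC = "mvc"
MATCHED = "matched"

PRE_STIMULUS_WINDOW = 0.25  # s
TWITCH_WINDOW = 0.15  # s


@dataclass
class TrialRecord:
    """One experimental trial: identity, trace, stimulus event times."""

    trial_id: str
    arm_id: str
    transfer_group: str
    posture: str
    trial_type: str  # "mvc" | "matched"
    target_level: float | None
    trace: MomentTrace
    stim_times: tuple[float, ...] = field(default_factory=tuple)
    subject_id: str | None = None

    def __post_init__(self):
        self.stim_times = tuple(float(t) for t in self.stim_times)
        if self.trial_type == MVC:
            if self.stim_times:
                raise ValidationError("maximum-effort trials carry no stimuli")
        elif self.trial_type == MATCHED:
            if len(self.stim_times) != 2:
                raise ValidationError("matched trials carry exactly two stimuli")
            if not self.stim_times[1] > self.stim_times[0]:
                raise ValidationError("stimulus times must be increasing")
        else:
            raise ValidationError(f"unknown trial_type {self.trial_type!r}")
        if self.subject_id is None:
            self.subject_id = self.arm_id


@dataclass(frozen=True)
class TwitchMeasurement:
    """One stimulus event reduced to (pre-stimulus moment, twitch amplitude)."""

    trial_id: str
    effort_context: float  # target effort fraction; 0 for the resting stimulus
    pre_stimulus_moment: float  # N·m
    twitch_amplitude: float  # N·m


def pre_stimulus_moment(
    trace: MomentTrace, stim_time: float, window: float = PRE_STIMULUS_WINDOW
) -> float:
    """Average moment maintained over ``window`` s prior to the stimulus."""
    try:
        return window_mean(trace, stim_time - window, window)
    except BoundsError as exc:
        raise BoundsError(
            f"need {window * 1e3:.0f} ms of trace before stimulus at {stim_time} s"
        ) from exc


def twitch_amplitude(
    trace: MomentTrace,
    stim_time: float,
    window: float = TWITCH_WINDOW,
    pre_window: float = PRE_STIMULUS_WINDOW,
) -> float:
    """Post-stimulus peak within ``window`` s minus the pre-stimulus moment.

    The search window ``[stim, stim + window]`` is closed on the right.
    """
    i0 = trace.index_at(stim_time, round_up=True)
    i1 = trace.index_at(stim_time + window, round_up=False)  # inclusive
    if i0 < 0 or i1 >= trace.n_samples or i1 < i0:
        raise BoundsError(
            f"need {window * 1e3:.0f} ms of trace after stimulus at {stim_time} s"
        )
    peak = float(np.max(trace.samples[i0 : i1 + 1]))
    return peak - pre_stimulus_moment(trace, stim_time, pre_window)


def extract_trial(trial: TrialRecord) -> list[TwitchMeasurement]:
    """Reduce one matched trial to its superimposed and resting measurements."""
    if trial.trial_type != MATCHED:
        raise MissingDataError(
            f"trial {trial.trial_id!r} is not a matched trial; nothing to extract"
        )
    stim_sup, stim_rest = trial.stim_times
    out = []
    for stim, effort in ((stim_sup, float(trial.target_level)), (stim_rest, 0.0)):
        pre = pre_stimulus_moment(trial.trace, stim)
        amp = twitch_amplitude(trial.trace, stim)
        if effort == 0.0 and amp > 0 and abs(pre) > 0.25 * amp:
            warnings.warn(
                f"trial {trial.trial_id!r}: resting baseline {pre:.3g} N*m is "
                f"large relative to the resting twitch {amp:.3g} N*m",
                QCWarning,
                stacklevel=2,
            )
        out.append(TwitchMeasurement(trial.trial_id, effort, pre, amp))
    return out


def max_voluntary_moment(
    trials: list[TrialRecord],
    window: float = 0.5,
    include_matched_100: bool = True,
    pre_stim_guard: float = 0.1,
) -> float:
    """Greatest 0.5-s sustained mean across qualifying maximal-effort trials.

    Pools the dedicated maximum-effort trials with the pre-stimulus
    portion of 100%-target matched trials (the voluntary segment before
    the first stimulus); ``include_matched_100=False`` restricts to the
    dedicated trials only.  The matched segment stops ``pre_stim_guard``
    seconds before the stimulus because zero-phase filtering spreads
    the evoked response backward in time.
    """
    candidates: list[MomentTrace] = []
    for t in trials:
        if t.trial_type == MVC:
            candidates.append(t.trace)
        elif (
            include_matched_100
            and t.trial_type == MATCHED
            and t.target_level is not None
            and np.isclose(t.target_level, 1.0)
        ):
            seg_end = t.stim_times[0] - pre_stim_guard
            if seg_end - t.trace.start_time >= window:
                candidates.append(t.trace.segment(t.trace.start_time, seg_end))
    if not candidates:
        raise MissingDataError(
            "no maximum-effort or 100%-target trials to estimate the maximum "
            "voluntary moment from"
        )
    return max(max_sustained_mean(tr, window)[0] for tr in candidates)
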