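"""Extrapolation to full activation and the voluntary-activation ratio.

For each arm x posture the superimposed twitch amplitudes (at 33%, 66%
and 100% target effort) and the six resting twitches closest to the
median are regressed on the voluntary pre-stimulus moment.  The fitted
line's x-intercept is the predicted moment at full motor-pool
recruitment, and

    VA = max voluntary moment / predicted moment.

Fits with R^2 < 0.80 (or a non-negative slope, where the x-intercept
is meaningless) are excluded but counted, never dropped silently.
VA values above 1 are preserved and flagged, not clamped — the linear
extrapolation can predict less than the measured maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .errors import MissingDataError, PipelineError
from .signal import CalibrationSpec, VOLTS, apply_calibration, lowpass_filter
from .twitch import (
    MATCHED,
    TrialRecord,
    TwitchMeasurement,
    extract_trial,
    max_voluntary_moment,
)

R2_THRESHOLD = 0.80
N_REST_TWITCHES = 6

REASON_OK = "ok"
REASON_LOW_R2 = "low_r2"
REASON_NONNEGATIVE_SLOPE = "nonnegative_slope"


@dataclass
class ExtrapolationFit:
    """Twitch-vs-voluntary-moment regression for one arm x posture."""

    arm_id: str
    posture: str
    slope: float  # N·m twitch per N·m voluntary; expected < 0
    intercept: float  # N·m, twitch at zero voluntary moment
    r_squared: float
    predicted_moment: float  # N·m; x-intercept; nan when slope >= 0
    n_points: int
    included: bool
    exclusion_reason: str = REASON_OK
    voluntary_moments: np.ndarray = field(default_factory=lambda: np.empty(0))
    twitch_amplitudes: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class VAResult:
    """Voluntary activation for one arm x posture, with QC status."""

    arm_id: str
    transfer_group: str
    posture: str
    max_voluntary_moment: float  # N·m
    predicted_moment: float  # N·m
    voluntary_activation: float  # fraction; nan when excluded
    qc_included: bool
    r_squared: float = float("nan")
    over_unity: bool = False
    reason: str = REASON_OK
    subject_id: str | None = None


def select_rest_twitches(
    rest_amplitudes: list[float] | np.ndarray, k: int = N_REST_TWITCHES
) -> list[int]:
    """Indices of the ``k`` resting twitches closest to the median.

    Only these enter the regression, for equal representation of the
    0%-effort condition.  Ties are broken by earlier trial order; with
    ``n <= k`` every index is returned.  Indices come back in trial
    order.
    """
    amps = np.asarray(rest_amplitudes, dtype=float)
    if amps.size == 0:
        raise MissingDataError("no resting twitch amplitudes to select from")
    if amps.size <= k:
        return list(range(amps.size))
    med = float(np.median(amps))
    order = np.argsort(np.abs(amps - med), kind="stable")
    return sorted(int(i) for i in order[:k])


def fit_extrapolation(
    measurements: list[TwitchMeasurement],
    selected_rest: list[TwitchMeasurement],
    r2_threshold: float = R2_THRESHOLD,
    arm_id: str = "",
    posture: str = "",
) -> ExtrapolationFit:
    """OLS of twitch amplitude on voluntary pre-stimulus moment.

    ``measurements`` are the superimposed points (effort > 0);
    ``selected_rest`` the median-selected resting points, entered at
    their measured (near-zero) pre-stimulus moments.  R^2 is the
    coefficient of determination of the simple linear fit.
    """
    points = [m for m in measurements if m.effort_context > 0] + list(selected_rest)
    x = np.array([m.pre_stimulus_moment for m in points], dtype=float)
    y = np.array([m.twitch_amplitude for m in points], dtype=float)
    if np.unique(x).size < 3:
        raise MissingDataError(
            f"need >= 3 distinct voluntary moments, got {np.unique(x).size}"
        )
    res = scipy.stats.linregress(x, y)
    slope, intercept = float(res.slope), float(res.intercept)
    r2 = float(res.rvalue) ** 2
    if slope >= 0:
        return ExtrapolationFit(
            arm_id, posture, slope, intercept, r2, float("nan"), x.size,
            included=False, exclusion_reason=REASON_NONNEGATIVE_SLOPE,
            voluntary_moments=x, twitch_amplitudes=y,
        )
    predicted = -intercept / slope
    included = r2 >= r2_threshold
    return ExtrapolationFit(
        arm_id, posture, slope, intercept, r2, predicted, x.size,
        included=included,
        exclusion_reason=REASON_OK if included else REASON_LOW_R2,
        voluntary_moments=x, twitch_amplitudes=y,
    )


def compute_va(
    max_voluntary: float,
    fit: ExtrapolationFit,
    transfer_group: str = "",
    subject_id: str | None = None,
) -> VAResult:
    """Voluntary activation = max voluntary moment / predicted moment.

    Excluded fits propagate as a missing VA with the fit's reason code;
    the moment itself is retained.
    """
    if not fit.included:
        return VAResult(
            fit.arm_id, transfer_group, fit.posture, max_voluntary,
            fit.predicted_moment, float("nan"), qc_included=False,
            r_squared=fit.r_squared, reason=fit.exclusion_reason,
            subject_id=subject_id,
        )
    va = max_voluntary / fit.predicted_moment
    return VAResult(
        fit.arm_id, transfer_group, fit.posture, max_voluntary,
        fit.predicted_moment, va, qc_included=True, r_squared=fit.r_squared,
        over_unity=va > 1.0, subject_id=subject_id,
    )


def run_arm_posture(
    trials: list[TrialRecord],
    calibration: CalibrationSpec | None = None,
    cutoff_hz: float = 80.0,
    filter_order: int = 4,
    r2_threshold: float = R2_THRESHOLD,
    n_rest: int = N_REST_TWITCHES,
    include_matched_100: bool = True,
) -> tuple[VAResult, ExtrapolationFit]:
    """Full pipeline for the trials of one arm x posture.

    calibrate (if raw volts) → filter → extract twitches → select rest
    twitches → fit extrapolation → maximum voluntary moment → VA.
    Deterministic given its inputs; stage failures surface as
    :class:`PipelineError` tagged with the stage name.
    """
    if not trials:
        raise MissingDataError("no trials supplied")
    ids = {(t.arm_id, t.posture) for t in trials}
    if len(ids) != 1:
        raise PipelineError("validate", f"trials span multiple arm x posture: {ids}")

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except MissingDataError as exc:
            raise PipelineError(name, str(exc)) from exc

    prepped = []
    for t in trials:
        trace = t.trace
        if trace.units == VOLTS:
            if calibration is None:
                raise PipelineError(
                    "calibrate", f"trial {t.trial_id!r} is in volts but no "
                    "calibration was provided"
                )
            trace = apply_calibration(trace, calibration)
        trace = lowpass_filter(trace, cutoff_hz, filter_order)
        prepped.append(
            TrialRecord(
                t.trial_id, t.arm_id, t.transfer_group, t.posture, t.trial_type,
                t.target_level, trace, t.stim_times, t.subject_id,
            )
        )

    matched = [t for t in prepped if t.trial_type == MATCHED]
    if not matched:
        raise PipelineError("extract", "no matched trials with stimulation")
    measurements: list[TwitchMeasurement] = []
    for t in matched:
        measurements.extend(stage("extract", extract_trial, t))

    superimposed = [m for m in measurements if m.effort_context > 0]
    rest = [m for m in measurements if m.effort_context == 0]
    sel_idx = stage(
        "select_rest", select_rest_twitches, [m.twitch_amplitude for m in rest], n_rest
    )
    selected_rest = [rest[i] for i in sel_idx]

    t0 = prepped[0]
    fit = stage(
        "fit", fit_extrapolation, superimposed, selected_rest, r2_threshold,
        t0.arm_id, t0.posture,
    )
    mvm = stage(
        "max_voluntary_moment", max_voluntary_moment, prepped,
        include_matched_100=include_matched_100,
    )
    result = compute_va(mvm, fit, t0.transfer_group, t0.subject_id)
    return result, fit
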