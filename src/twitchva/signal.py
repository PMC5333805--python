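"""Calibration, filtering and windowed statistics for moment traces.

A :class:`MomentTrace` is a uniformly sampled elbow-moment time series.
Raw transducer output arrives in volts and is mapped to N·m by a linear
calibration; traces are then low-pass filtered (4th-order Butterworth,
80 Hz cutoff, applied forward and backward so the net phase shift is
zero) before any windowed statistic is taken.

Window convention: sample ``i`` sits at ``start_time + i / sampling_rate``
and a window ``[start, start + duration)`` is half-open on the right.
The one exception is the twitch-peak search window, which is closed
(see :mod:`twitchva.twitch`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.signal

from .errors import BoundsError, ConfigurationError, ParameterError, UnitsError

VOLTS = "volts"
NEWTON_METERS = "newton_meters"


@dataclass
class MomentTrace:
    """Uniformly sampled moment (or raw voltage) time series."""

    samples: np.ndarray
    sampling_rate: float
    units: str = NEWTON_METERS
    start_time: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ParameterError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ParameterError("samples contain missing/non-finite values")
        if not self.sampling_rate > 0:
            raise ParameterError("sampling_rate must be positive")
        if self.units not in (VOLTS, NEWTON_METERS):
            raise UnitsError(f"unknown units {self.units!r}")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def end_time(self) -> float:
        """Time just past the last sample (exclusive extent)."""
        return self.start_time + self.duration

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate

    def index_at(self, time: float, *, round_up: bool) -> int:
        """Grid index of ``time``; ceil or floor with half-sample tolerance."""
        x = (time - self.start_time) * self.sampling_rate
        i = np.ceil(x - 1e-9) if round_up else np.floor(x + 1e-9)
        return int(i)

    def segment(self, start: float, stop: float) -> "MomentTrace":
        """Sub-trace of samples with times in ``[start, stop)``."""
        i0 = self.index_at(start, round_up=True)
        i1 = self.index_at(stop, round_up=True)
        if i0 < 0 or i1 > self.n_samples or i1 <= i0:
            raise BoundsError(
                f"segment [{start}, {stop}) outside trace "
                f"[{self.start_time}, {self.end_time})"
            )
        return replace(
            self,
            samples=self.samples[i0:i1].copy(),
            start_time=self.start_time + i0 / self.sampling_rate,
        )


@dataclass(frozen=True)
class CalibrationSpec:
    """Linear volts → N·m calibration: moment = gain·v + offset."""

    gain: float  # N·m per volt
    offset: float = 0.0  # N·m

    def __post_init__(self):
        if self.gain == 0:
            raise ParameterError("calibration gain must be non-zero")


def apply_calibration(trace: MomentTrace, cal: CalibrationSpec) -> MomentTrace:
    """Map a raw-voltage trace to N·m with the affine calibration."""
    if trace.units != VOLTS:
        raise UnitsError(f"calibration expects volts, got {trace.units!r}")
    return replace(
        trace, samples=cal.gain * trace.samples + cal.offset, units=NEWTON_METERS
    )


def lowpass_filter(
    trace: MomentTrace, cutoff_hz: float = 80.0, order: int = 4
) -> MomentTrace:
    """Zero-phase low-pass Butterworth filter.

    The filter is designed at ``order`` and applied forward and backward
    (``sosfiltfilt``), giving zero net phase shift and unit DC gain.
    Edges are handled by odd-reflection padding well beyond 3x the
    filter order, which suppresses startup transients at trial onset.
    """
    nyquist = trace.sampling_rate / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise ConfigurationError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyquist} Hz)"
        )
    sos = scipy.signal.butter(order, cutoff_hz, fs=trace.sampling_rate, output="sos")
    return replace(trace, samples=scipy.signal.sosfiltfilt(sos, trace.samples))


def window_mean(trace: MomentTrace, start: float, duration: float) -> float:
    """Mean of samples with timestamps in the half-open ``[start, start+duration)``."""
    if duration <= 0:
        raise BoundsError("window duration must be positive")
    i0 = trace.index_at(start, round_up=True)
    i1 = trace.index_at(start + duration, round_up=True)
    if i0 < 0 or i1 > trace.n_samples or i1 <= i0:
        raise BoundsError(
            f"window [{start}, {start + duration}) outside trace "
            f"[{trace.start_time}, {trace.end_time})"
        )
    return float(np.mean(trace.samples[i0:i1]))


def max_sustained_mean(
    trace: MomentTrace, window: float = 0.5
) -> tuple[float, float]:
    """Greatest average moment maintained over ``window`` seconds.

    Slides a ``window``-long averaging window across the trace in
    one-sample steps and returns ``(value, window_start_time)``;
    ties go to the earliest window.
    """
    w = int(round(window * trace.sampling_rate))
    if w < 1 or w > trace.n_samples:
        raise BoundsError(
            f"window of {window} s does not fit a {trace.duration} s trace"
        )
    means = np.lib.stride_tricks.sliding_window_view(trace.samples, w).mean(axis=-1)
    i = int(np.argmax(means))  # argmax returns the first maximum
    return float(means[i]), trace.start_time + i / trace.sampling_rate
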