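"""Run configuration with the protocol's analysis constants baked in.

Defaults mirror the measurement conventions the pipeline is built
around: 1000-Hz sampling, 4th-order 80-Hz zero-phase Butterworth
filtering, 0.5-s sustained-maximum window, 250-ms pre-stimulus window,
150-ms twitch window, six median-selected rest twitches, and an R^2
inclusion threshold of 0.80.  Any deviation is echoed in the run log
header for provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError, ValidationError
from .signal import CalibrationSpec
from .simulate import POSTURES, TRANSFER_GROUPS, ArmGroundTruth, ProtocolSpec


@dataclass
class RunConfig:
    """All knobs of a reproducible simulate/analyze run."""

    manifest: str | None = None
    trace_dir: str | None = None
    output_dir: str = "twitchva_out"
    calibration_gain: float = 1.0  # N·m per volt
    calibration_offset: float = 0.0  # N·m
    filter_cutoff_hz: float = 80.0
    filter_order: int = 4
    pre_stimulus_window_s: float = 0.25
    twitch_window_s: float = 0.15
    sustained_window_s: float = 0.5
    n_rest_twitches: int = 6
    r2_threshold: float = 0.80
    include_matched_100: bool = True
    heteroscedastic: bool = True
    nested_subject: bool = True
    alpha: float = 0.05
    seed: int = 0
    protocol: ProtocolSpec = field(default_factory=ProtocolSpec)
    ground_truths: list[ArmGroundTruth] = field(default_factory=list)

    def __post_init__(self):
        for name in ("pre_stimulus_window_s", "twitch_window_s", "sustained_window_s"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be positive")
        if not 0 <= self.r2_threshold <= 1:
            raise ConfigurationError("r2_threshold must lie in [0, 1]")
        if self.n_rest_twitches < 1:
            raise ConfigurationError("n_rest_twitches must be >= 1")

    @property
    def calibration(self) -> CalibrationSpec:
        return CalibrationSpec(self.calibration_gain, self.calibration_offset)

    def non_default_settings(self) -> dict:
        """Analysis constants that deviate from the defaults (for the log)."""
        ref = RunConfig()
        out = {}
        for f in dataclasses.fields(RunConfig):
            if f.name in ("manifest", "trace_dir", "output_dir", "seed",
                          "protocol", "ground_truths"):
                continue
            if getattr(self, f.name) != getattr(ref, f.name):
                out[f.name] = getattr(self, f.name)
        return out


def _ground_truth_from_dict(d: dict) -> ArmGroundTruth:
    if d.get("posture") not in POSTURES:
        raise ValidationError(
            f"posture {d.get('posture')!r} invalid; allowed: {list(POSTURES)}"
        )
    if d.get("transfer_group") not in TRANSFER_GROUPS:
        raise ValidationError(
            f"transfer_group {d.get('transfer_group')!r} invalid; "
            f"allowed: {list(TRANSFER_GROUPS)}"
        )
    return ArmGroundTruth(**d)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML (or JSON — YAML is a superset) run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    protocol = ProtocolSpec(**{
        k: tuple(v) if k == "target_levels" else v
        for k, v in (raw.pop("protocol", {}) or {}).items()
    })
    gts = [_ground_truth_from_dict(d) for d in raw.pop("ground_truths", []) or []]
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(protocol=protocol, ground_truths=gts, **raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    d = dataclasses.asdict(config)
    d["protocol"]["target_levels"] = list(d["protocol"]["target_levels"])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
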