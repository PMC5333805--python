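"""CSV plumbing: traces, manifests, measurements and results tables.

No community standard exists for dynamometry traces, so everything is
plain CSV with fixed, documented column names:

* trace files — ``time_s`` plus one value column named for its units
  (``moment_nm`` or ``volts``);
* manifest — one row per trial: trial_id, arm_id, subject_id,
  transfer_group, posture, trial_type, target_level, stim1_time_s,
  stim2_time_s, trace_path (relative to the manifest);
* measurements — tidy per-stimulus table;
* results — one row per arm x posture with VA and QC status.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .activation import ExtrapolationFit, VAResult
from .errors import ValidationError
from .signal import NEWTON_METERS, VOLTS, MomentTrace
from .simulate import StudyDataset
from .twitch import MVC, TrialRecord, TwitchMeasurement

_UNIT_COLUMNS = {NEWTON_METERS: "moment_nm", VOLTS: "volts"}
_COLUMN_UNITS = {v: k for k, v in _UNIT_COLUMNS.items()}


def write_trace_csv(trace: MomentTrace, path: str | Path) -> None:
    df = pd.DataFrame(
        {"time_s": trace.times, _UNIT_COLUMNS[trace.units]: trace.samples}
    )
    df.to_csv(path, index=False, float_format="%.9g")


def read_trace_csv(path: str | Path) -> MomentTrace:
    """Read a two-column trace CSV; units inferred from the value column name."""
    df = pd.read_csv(path)
    if df.shape[1] < 2 or df.columns[0] != "time_s":
        raise ValidationError(f"{path}: expected columns time_s,<value>")
    if df.isna().any().any():
        raise ValidationError(f"{path}: trace contains missing values")
    t = df["time_s"].to_numpy(dtype=float)
    value_col = df.columns[1]
    units = _COLUMN_UNITS.get(value_col, NEWTON_METERS)
    dt = np.diff(t)
    if t.size < 2 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValidationError(f"{path}: time column is not uniformly sampled")
    fs = 1.0 / float(np.median(dt))
    return MomentTrace(
        df[value_col].to_numpy(dtype=float), fs, units, start_time=float(t[0])
    )


def write_study(dataset: StudyDataset, outdir: str | Path) -> Path:
    """Write traces/, manifest.csv and ground_truth.csv; returns manifest path."""
    outdir = Path(outdir)
    (outdir / "traces").mkdir(parents=True, exist_ok=True)
    for trial in dataset.trials:
        write_trace_csv(trial.trace, outdir / "traces" / f"{trial.trial_id}.csv")
    manifest_path = outdir / "manifest.csv"
    dataset.manifest.to_csv(manifest_path, index=False)
    dataset.ground_truth.to_csv(outdir / "ground_truth.csv", index=False)
    return manifest_path


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {
        "trial_id", "arm_id", "transfer_group", "posture", "trial_type",
        "target_level", "stim1_time_s", "stim2_time_s", "trace_path",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: manifest missing columns {sorted(missing)}")
    if df.empty:
        raise ValidationError(f"{path}: no trials in manifest")
    return df


def load_trials(manifest_path: str | Path) -> list[TrialRecord]:
    """Materialise TrialRecords from a manifest and its trace files."""
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    base = manifest_path.parent
    trials = []
    for row in df.itertuples(index=False):
        trace_file = base / row.trace_path
        if not trace_file.exists():
            raise ValidationError(
                f"trial {row.trial_id!r}: trace file {trace_file} not found"
            )
        stim_times: tuple[float, ...] = ()
        if row.trial_type != MVC:
            stim_times = (float(row.stim1_time_s), float(row.stim2_time_s))
        trials.append(
            TrialRecord(
                trial_id=str(row.trial_id),
                arm_id=str(row.arm_id),
                transfer_group=str(row.transfer_group),
                posture=str(row.posture),
                trial_type=str(row.trial_type),
                target_level=None if pd.isna(row.target_level) else float(row.target_level),
                trace=read_trace_csv(trace_file),
                stim_times=stim_times,
                subject_id=str(getattr(row, "subject_id", row.arm_id)),
            )
        )
    return trials


def measurements_frame(
    records: list[tuple[TrialRecord, TwitchMeasurement]]
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "trial_id": m.trial_id,
                "arm_id": t.arm_id,
                "posture": t.posture,
                "effort_context": m.effort_context,
                "pre_stimulus_moment_nm": m.pre_stimulus_moment,
                "twitch_amplitude_nm": m.twitch_amplitude,
            }
            for t, m in records
        ]
    )


def results_frame(results: list[VAResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "arm_id": r.arm_id,
                "subject_id": r.subject_id,
                "transfer_group": r.transfer_group,
                "posture": r.posture,
                "max_voluntary_moment_nm": r.max_voluntary_moment,
                "predicted_moment_nm": r.predicted_moment,
                "voluntary_activation": r.voluntary_activation,
                "r_squared": r.r_squared,
                "qc_included": r.qc_included,
                "over_unity": r.over_unity,
                "reason": r.reason,
            }
            for r in results
        ]
    )


def diagnostics_frame(fits: list[ExtrapolationFit]) -> pd.DataFrame:
    rows = []
    for f in fits:
        for x, y in zip(f.voluntary_moments, f.twitch_amplitudes):
            rows.append(
                {
                    "arm_id": f.arm_id,
                    "posture": f.posture,
                    "voluntary_moment_nm": x,
                    "twitch_amplitude_nm": y,
                    "slope": f.slope,
                    "intercept": f.intercept,
                    "r_squared": f.r_squared,
                    "included": f.included,
                }
            )
    return pd.DataFrame(rows)
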