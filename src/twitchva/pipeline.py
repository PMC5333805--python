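"""End-to-end composition: trials in, per-condition VA and group stats out."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .activation import ExtrapolationFit, VAResult, run_arm_posture
from .config import RunConfig
from .errors import MissingDataError, PipelineError
from .stats import EffectTestResult, fit_group_model, group_summary
from .twitch import MATCHED, TrialRecord, extract_trial

log = logging.getLogger("twitchva")


@dataclass
class StudyAnalysis:
    """Everything the analysis produces for one study."""

    results: pd.DataFrame  # one row per arm x posture
    va_results: list[VAResult]
    fits: list[ExtrapolationFit]
    measurements: pd.DataFrame
    summaries: dict = field(default_factory=dict)  # response -> summary frame
    effects: dict = field(default_factory=dict)  # response -> [EffectTestResult]

    @property
    def n_excluded(self) -> int:
        return sum(not r.qc_included for r in self.va_results)


def analyze_trials(trials: list[TrialRecord], config: RunConfig | None = None) -> StudyAnalysis:
    """Run the full per-condition pipeline over every arm x posture group.

    Conditions whose fit fails QC are retained with missing VA and a
    machine-parsable reason code; each exclusion is logged.  Group
    statistics are fitted whenever the design supports them (both
    transfer groups and at least two postures).
    """
    from .io import measurements_frame, results_frame  # local: avoid cycle

    if not trials:
        raise MissingDataError("no trials to analyze")
    cfg = config or RunConfig()

    by_condition: dict[tuple[str, str], list[TrialRecord]] = {}
    for t in trials:
        by_condition.setdefault((t.arm_id, t.posture), []).append(t)

    va_results, fits, meas_records = [], [], []
    for (arm, posture), group in sorted(by_condition.items()):
        result, fit = run_arm_posture(
            group,
            calibration=cfg.calibration,
            cutoff_hz=cfg.filter_cutoff_hz,
            filter_order=cfg.filter_order,
            r2_threshold=cfg.r2_threshold,
            n_rest=cfg.n_rest_twitches,
            include_matched_100=cfg.include_matched_100,
        )
        va_results.append(result)
        fits.append(fit)
        if not result.qc_included:
            log.warning(
                "excluded arm=%s posture=%s reason=%s r2=%.3f",
                arm, posture, result.reason, result.r_squared,
            )
        for t in group:
            if t.trial_type == MATCHED:
                for m in extract_trial(t):
                    meas_records.append((t, m))

    results = results_frame(va_results)
    analysis = StudyAnalysis(
        results=results,
        va_results=va_results,
        fits=fits,
        measurements=measurements_frame(meas_records),
    )
    log.info(
        "analyzed %d arm x posture conditions; %d excluded by QC",
        len(va_results), analysis.n_excluded,
    )

    table = results.rename(
        columns={
            "max_voluntary_moment_nm": "max_voluntary_moment",
            "predicted_moment_nm": "predicted_moment",
        }
    )
    for response in ("va", "moment"):
        analysis.summaries[response] = group_summary(table, response)
        if (
            table["transfer_group"].nunique() >= 2
            and table["posture"].nunique() >= 2
        ):
            try:
                _, effects = fit_group_model(
                    table,
                    response,
                    heteroscedastic=cfg.heteroscedastic,
                    nested_subject=cfg.nested_subject,
                    alpha=cfg.alpha,
                )
                analysis.effects[response] = effects
            except PipelineError:
                raise
    return analysis


def effects_report(effects: dict[str, list[EffectTestResult]]) -> dict:
    """JSON-serialisable view of the statistical tests."""
    out = {}
    for response, tests in effects.items():
        out[response] = [
            {
                "effect": t.effect,
                "F": t.f_statistic,
                "df": [t.df_num, t.df_den],
                "p": t.p_value,
                "posthoc": [
                    {
                        "contrast": c.contrast,
                        "t": c.t,
                        "df": c.df,
                        "p_adjusted": c.p_adjusted,
                    }
                    for c in t.posthoc
                ],
            }
            for t in tests
        ]
    return out
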