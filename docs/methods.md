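# Methods

## Measurement model

The package analyses isometric joint-moment recordings from an
interpolated-twitch protocol. Per arm × posture the protocol comprises
three 5-s maximum voluntary efforts followed by six moment-matching
trials at each of 33%, 66% and 100% of the recorded maximum. Every
matching trial carries two single supramaximal stimuli: one delivered
once the subject has held the target within ±5% for 250 ms, and one
7 s later with the arm relaxed (the 0%-effort response).

Raw transducer voltage (1000 Hz) is mapped to N·m by a linear
calibration and filtered with a 4th-order low-pass Butterworth at
80 Hz, applied forward and backward. Zero-phase filtering was chosen
because the twitch is localised in a 150-ms window and a causal
filter's group delay would bias it; the 4th order is the design order
of the applied filter. Edge transients are suppressed by
odd-reflection padding well beyond three filter lengths.

Windows are half-open `[start, start+duration)` with sample *i* at
`start_time + i/fs`; the single exception is the twitch-peak search
window, closed at its right edge (the 150-ms boundary sample is a
legitimate peak candidate). Per stimulus the pipeline computes the
pre-stimulus moment (250-ms mean, stimulus sample excluded) and the
twitch amplitude (post-stimulus 150-ms maximum minus pre-stimulus
moment). Negative amplitudes are retained — near full activation the
evoked increment can vanish into the noise floor and clamping would
bias the regression.

The maximum voluntary moment is the greatest 0.5-s sliding-window mean
(one-sample step, ties to the earliest window) pooled over the
dedicated maximal trials and the pre-stimulus segment of 100%-target
matching trials; a configuration switch restricts to the dedicated
trials. The pooled segment ends 100 ms before the stimulus because the
zero-phase filter spreads the evoked response backward in time;
without the guard the leaked twitch inflates the sustained mean by
~1.5 × 10⁻⁶ of the full-activation moment.

## Extrapolation and voluntary activation

Twitch amplitude is regressed on voluntary pre-stimulus moment by
ordinary least squares over the superimposed points plus the six
resting twitches closest to the median amplitude (equal representation
of rest; ties broken by trial order; all are used when six or fewer
exist). Resting points enter at their measured near-zero baselines
rather than exactly zero, which uses the data as recorded and is
robust to baseline offsets. The predicted full-activation moment is
the fitted line's x-intercept, and

    VA = max voluntary moment / predicted moment,

reported as a fraction, preserved and flagged (not clamped) above 1.
R² is the coefficient of determination of the simple fit. Fits with
R² < 0.80 are excluded; a non-negative slope is flagged degenerate
(the x-intercept is meaningless) and excluded rather than fatal.
Excluded conditions are counted and propagate a machine-parsable
reason code with their measured moment retained.

## Synthetic experiments

The generator emulates the protocol under the linear occlusion model
the technique assumes: with voluntary drive `v = effort × true_va`,
the plateau is `v × M_full` and the superimposed twitch amplitude is
`T0 (1 − v)` (an optional curvature term bends this for robustness
studies; default 0). The twitch waveform is `α (t/τ) e^(1−t/τ)` with
τ = 70 ms by default so the peak falls inside the 150-ms window; the
waveform shape is a modelling choice, not a measured quantity.
Moment-matching imperfection is uniform jitter within the ±5% hold
tolerance at submaximal targets; at the 100% target the subject simply
pushes maximally (a maximal effort is not "matched"), so the achieved
drive is exactly `true_va`. Effort ramps are raised-cosine (smooth
onsets are realistic and avoid filter ringing at plateau corners).
Noise is white Gaussian per sample, default sd 2% of `M_full`, plus an
optional single-frequency tremor gated by the effort envelope (default
off) and an optional linear plateau drift (default off — fatigue
behaviour across maximal efforts is deliberately not modelled).
`T0` defaults to 20% of `M_full`, in the range reported for
supramaximal single twitches relative to maximal moment. Posture is a
categorical label only; posture-specific ground truths are supplied by
the caller, not derived from joint geometry. Identical seeds reproduce
traces bit-identically (per-trial seeds are spawned from the study
seed).

What the simulator does *not* emulate — stimulus-intensity titration,
M-wave/artifact contamination, antagonist co-contraction, fatigue,
serially correlated physiological noise — bounds what passing recovery
tests show: they validate the analysis under the technique's own
assumptions, not the assumptions themselves.

### A known property: noise biases VA downward

The twitch estimator is a windowed maximum, so broadband noise inflates
every twitch amplitude by roughly the expected maximum of the filtered
noise near the peak (~1.6× its sd under the defaults). Because this
offset raises the regression intercept, the extrapolated
full-activation moment grows and VA falls: under the default 2% white
noise the recovered VA carries a systematic bias of about −0.06 × VA
(mean absolute error ≈ 0.05 at study-like activation levels, measured
by the acceptance suite's Monte-Carlo test). Noiseless recovery is
exact to < 10⁻⁷, confirming the bias is a property of the
peak-detection estimator under noise, not of the implementation.

## Group statistics

Per response (VA or maximal moment) the model has fixed effects
transfer, posture and their interaction (sum-to-zero coding), random
intercepts for subject and arm-within-subject (some participants
contribute both arms), and residual variances that differ by transfer
group — the grouping whose spreads visibly differ. Parameters are
estimated by REML over per-subject covariance blocks; when every
subject contributed a single arm the subject level is collapsed
automatically (the two variances are otherwise unidentifiable).
Type-III Wald F statistics use containment-style denominator df
(between-arm effects: `n_arms − 2`; within-arm effects:
`N − n_arms − 2(k−1)`); on balanced homoscedastic data these reproduce
the classical split-plot ANOVA exactly (verified against an
independent classical implementation, and against R's nlme with
group-wise variance weights on a heteroscedastic fixture). Denominator
df conventions differ across software, so df are reported, not
asserted. Post-hoc pairwise contrasts of cell means are t tests on the
fitted model with Bonferroni adjustment (p × m, capped at 1), run when
the corresponding F test is significant at α = 0.05. Null calibration:
over 500 simulated null replicates at study-like n the transfer effect
rejected at 4.8% for nominal α = 5%.

`deterioration_backcorrect(m, f) = m / (1 − f)` undoes an assumed
fractional strength loss, e.g. a 2.74 N·m group mean under 16%
deterioration back-corrects to 3.26 N·m.

## Problem sizes and numerical choices

Recovery tests use the full default protocol (21 trials per condition,
10-s matched trials at 1000 Hz); Monte-Carlo checks use 50 seeds per
activation level and 500 replicates for null calibration, sizes chosen
to give stable estimates at interactive runtimes. The REML objective
is optimised by Nelder-Mead on log-variances (bounded to ±30 in the
exponent) from a moment-based start; Cholesky failures and
sign-degenerate normal matrices return a large penalty. OLS quantities
agree with closed-form normal equations to 10⁻¹⁰; window statistics
agree exactly with exhaustive scans. Degenerate inputs (empty trials,
windows outside the trace, fewer than three distinct voluntary
moments, saturated designs) raise typed errors naming the failing
stage.
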