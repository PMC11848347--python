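# Methods

This note documents the models and procedures `sleepmicro` implements, the
parameter choices that matter, what the synthetic generators emulate (and
what they do not), and the numerical decisions behind the implementation.

## Coordinate and unit conventions

All amplitudes are microvolts; all times are seconds from recording start;
intervals are half-open `[start, end)`; hypnogram epoch *i* covers
`[30·i, 30·(i+1))`. The hypnogram file is the source of truth for sleep
stages — the package never re-scores sleep.

## Staging layer

**Sleep cycles.** A cycle is a run of NREM epochs followed by a run of REM
epochs, with at least 15 min of NREM and at least 5 min of REM — relaxed
to 1 min of REM for the first cycle of the night. Cycles are taken
greedily from recording start; interleaved W/N1 epochs inside a candidate
NREM run are tolerated but do not count toward the 15-min requirement
(only N2/N3 epochs do), and the REM phase extends to the next N2/N3
epoch. Epochs of failed candidates belong to no cycle.

**Artifact tagging** covers the two rule-expressible aberration classes:

* *flatline*: |x| below ε (default 1 µV) sustained strictly longer than
  1 s;
* *popping / muscle burst*: the 0.2-s local peak amplitude above a cap
  (default 300 µV) for longer than 1 s. The local-peak formulation is used
  because a broadband burst crosses zero constantly; requiring the raw
  sample to stay above the cap would never fire.

A third rule approximates visually scored micro-arousals: the ratio of
8–30 Hz to 0.5–8 Hz power in a 3-s sliding window exceeding a multiple
(default 4×) of its NREM median, sustained longer than 3 s. Because this
event class is ordinarily scored by eye, the rule is **off by default**
and exercised only on synthetic data.

**Architecture.** TST is the minutes in N1/N2/N3/REM inside the lights
interval; efficiency is 100·TST/time-in-bed; SOL is lights-off to the
first sleep epoch; WASO counts wake epochs after sleep onset. With zero
TST, efficiency is reported as 0 and stage percentages as missing.

## Slow-oscillation detector

The frontal signal is band-passed 0.16–1.25 Hz with a 2nd-order
Butterworth applied forward–backward (zero phase). Candidates are the
intervals between successive positive-to-negative zero crossings (crossing
times linearly interpolated between bracketing samples) lasting
0.8–2.0 s; the trough is the candidate minimum and the peak is the
maximum *after* the trough (trough-first convention). The amplitude gate
keeps candidates whose trough-to-peak amplitude **strictly exceeds** the
75th percentile (linear-interpolation quantile) of the duration-qualifying
candidate pool, computed per channel per recording over artifact-free
N2/N3 sleep only. Strictness matters in the degenerate equal-amplitude
case: when all candidates tie, none survives. With fewer than 4
candidates the percentile is unstable, so the detector warns and returns
nothing. Candidates touching a non-N2/N3 epoch or an artifact interval
are dropped before the percentile is computed (conservative: avoids stage
ambiguity). Whether the original percentile should be pooled across the
two frontal channels is unknowable from the protocol; per-channel is the
default and configurable.

Note the gate is *relative*: the detector always returns the top quartile
of whatever qualifies on duration, so on a quiet recording it reports the
strongest background fluctuations. Its absolute validity rests on the
recording actually containing slow-wave sleep; recall on injected
high-amplitude events is the tested property, precision is not a contract.

## Spindle detector

The central signal is band-passed 9–16 Hz (2nd-order Butterworth,
forward–backward); the envelope is a 0.2-s centered sliding RMS smoothed
by a 0.2-s centered moving average (edges use shrunken windows so output
length equals input length). The threshold is mean + k·SD (default
k = 1.5) of the smoothed envelope over artifact-free N2+N3 samples of the
same channel and recording — the standard reading of "RMS exceeding 1.5
SDs". Supra-threshold runs separated by gaps shorter than 0.1 s are
merged (envelope ripple otherwise splits single spindles; configurable,
default on), then runs lasting 0.5–3.0 s become events. Per event:
PTP amplitude (max − min of the filtered segment), power (mean squared
filtered amplitude, µV²), energy (power × duration, µV²·s — both are
computed because "power" and "energy" are used interchangeably in the
field; mean power is the default export), and peak power frequency
(periodogram of the filtered segment zero-padded to ≥ 1 s, i.e. ≤ 1 Hz
resolution, restricted to the band). Event stage is the stage of the
epoch containing the event midpoint. The construction is scale-invariant:
scaling the signal by λ > 0 scales envelope and threshold together and
leaves the event set unchanged.

## Event metrics

Density is count per artifact-free 30-s epoch of the analyzed stage set —
the same denominator everywhere. Channel-level metrics are computed per
channel and averaged with equal weights ("average" mode, default), which
keeps densities interpretable when one channel is partially masked; a
"pooled" mode (events and epochs pooled before dividing) is available.
Counts are summed across channels; means of empty channels are excluded;
all means are missing when no events exist. Events straddling an epoch
boundary count toward the epoch containing their midpoint.

## Statistics layer

**Robust GLMs.** Gaussian models are fitted by least squares, binomial by
IRLS; variances use the Huber/White sandwich. HC1 (n/(n−k) scaling) is
the default flavor, HC0/HC3 selectable. Confidence intervals are
β ± z₀.₉₇₅·SE. Diagnostics recorded per model: VIFs of the non-intercept
design columns (from the inverse correlation matrix; models are expected
to keep VIF < 2), and Shapiro–Wilk p of the response residuals (gaussian
only; capped at 5000 observations by decimation). A rank-deficient design
raises an error naming the collinear terms. Fewer than 10 observations
per modelled variable warns but does not error; the composed battery
skips such cells instead.

**Transformation.** `tukey_ladder_select` evaluates
λ ∈ {−2, −1, −½, 0 (log), ½, 1, 2}, sign-flipping negative rungs so every
transform is monotone increasing, and picks the rung maximizing the
Shapiro–Wilk W of the transformed sample. Rungs outside the data's domain
are skipped with a warning. In the battery, outcomes listed in
`transform_outcomes` (default: the pTau181/Aβ42 ratio, the one ratio
whose residuals are expected to be skewed) are re-fitted under the
selected transform when residual normality fails at α = 0.05.

**FDR.** Benjamini–Hochberg step-up via statsmodels; the family is all
tests sharing one outcome (one outcome × all six metrics), configurable.

**Decline odds.** Decline is MMSE(36) < MMSE(0) on complete cases; a
logistic model with the metric plus age/sex/AHI gives OR = exp(β) per
unit of the metric. Constant indicators and perfect separation raise.

**Mediation.** Three OLS stages, covariates in each:
mediator ~ exposure (a); outcome ~ exposure + mediator (b, c′);
outcome ~ exposure (c). Sobel z = ab/√(b²SEₐ² + a²SE_b²); Goodman-1 adds
and Goodman-2 subtracts SEₐ²SE_b² under the root. Proportion mediated is
ab/c, the indirect/direct ratio ab/c′; opposite signs of ab and c′ are
flagged as suppression. Conventional OLS standard errors feed the Sobel
statistics (matching the classic implementation of the test); the linear
identity c = c′ + ab then holds to numerical precision on any
complete-case fit. The battery runs mediation with the pTau181/Aβ42 ratio
as exposure and spindle density / SO duration as mediators.

**Moderation.** The interaction GLM adds exposure×moderator to the robust
model; simple slopes of the exposure are reported at the moderator's
25th/50th/75th percentiles with delta-method SEs from the robust
covariance. Covariates are included by default.

## Synthetic EEG generator

Background is 1/f-amplitude (pink) Gaussian noise — realistic enough that
envelope thresholds and the SO percentile gate are exercised nontrivially
— with default SD 5 µV. Spindles are Hann-windowed (waxing–waning)
sinusoids with specified PTP amplitude and carrier in 9–16 Hz; SOs are
single biphasic cycles (trough phase first, so the event spans successive
positive-to-negative zero crossings) with specified trough-to-peak
amplitude and carrier ≤ 1.25 Hz. Artifacts are flatlines (zeroed signal)
and broadband bursts. Events are only injectable into N2/N3 epochs —
planning one into Wake/REM is an error rather than a silently undetectable
event. All randomness flows through one explicit `numpy` generator;
identical seeds give bit-identical signals.

The benchmark validation night is 30 min of N2 at 256 Hz with 40 spindles
(12 Hz, 1 s, 40 µV PTP) on C3 and 50 SOs (0.8 Hz, 150 µV PTP) on F3 over
5 µV pink noise. 256 Hz keeps the benchmark fast while comfortably
resolving the 9–16 Hz band; clinical recordings at 512 Hz go through the
identical code path.

What the generator does **not** emulate: real spindle frequency chirp and
amplitude variability, SO–spindle phase coupling, K-complexes, EOG/EMG
cross-talk, slow drift and electrode impedance changes, or full-night
stage dynamics. Passing recovery tests therefore demonstrates algorithmic
correctness of the detection rules, not clinical-grade performance on
noisy patient data — the manual-review export exists precisely because
the original workflow includes visual confirmation.

## Synthetic cohort generator

The structural core is

    mediator = a·exposure + ε,   ε ~ N(0, noise_sd²)
    outcome  = c′·exposure + b·mediator + γ·exposure·moderator + ε

with standard-normal latent exposure and moderator. Clinical columns are
anchored to a mild-to-moderate AD polysomnography cohort: age 74.7 ± 5,
balanced sex, AHI 33.7 ± 23 (truncated at 0), Aβ42 median 516 pg/mL
(lower with higher exposure), pTau181 median 82 and t-tau median
543 pg/mL (higher with exposure), MMSE 23.2 ± 2.4 at baseline drifting
−0.8/−2.5/−4.1 points at 12/24/36 months, ADAS-Cog ~28.5 at baseline.
The pTau181/Aβ42 ratio column is the literal quotient of the generated
biomarkers. Spindle metrics load on the mediator latent; cognitive
follow-ups load on the outcome latent; so under an all-null configuration
every metric–outcome and metric–biomarker association is exactly null —
the property the calibration tests rely on. `skew > 0` switches biomarker
marginals to right-skewed lognormal shapes. An optional logistic decline
generator (`decline_beta`) makes the 36-month decline indicator follow
logit P = intercept + β·spindle-density for odds-ratio recovery tests.
MMSE values are kept continuous (not integer-rounded) so regression
recovery tests are exact; rounding would only add quantization noise.

## Numerical choices

* **Zero-phase filtering** uses `sosfiltfilt` with padding scaled to three
  periods of the low cutoff (the default padding is far too short for a
  0.16 Hz filter), and the result is averaged with its time-reversed twin
  — making time-reversal symmetry exact by construction (IEEE addition
  commutes) at the cost of a second pass.
* **Sliding windows** (RMS, moving average) are centered, with shrunken
  windows at the edges; the implementation reduces strided views with the
  same summation order as a per-index recomputation, so oracle comparisons
  are exact, not approximate.
* **Zero crossings** are located by sign change between consecutive
  samples (positive to non-positive) with linear interpolation of the
  crossing time.
* **Quantiles** use linear interpolation (`numpy.percentile` default).
* **Degenerate inputs**: constant envelopes yield no spindles (threshold
  = mean); equal-amplitude SO candidates yield no SOs (strict gate);
  all-wake hypnograms make the spindle statistics domain empty, which is
  an error, and make architecture percentages missing.
* **EDF round trips** are exact to half a 16-bit quantization step of the
  channel's physical range.

## Problem sizes used in validation

Detector recovery uses the 30-min benchmark night (one CPU, seconds).
Operator oracles use 100 random signals of 40–300 samples. Null
calibration runs the full battery on 200 cohorts of n = 500 and the
moderation type-I check on 500 cohorts of n = 500; parameter recovery
uses single cohorts of n = 5000 and path tolerances of ±0.05
(≈3 Monte-Carlo SEs). These sizes make the whole validation reproducible
in minutes while keeping Monte-Carlo error well inside the stated
tolerances.

## Known limitations

* The detectors assume a referenced, µV-scaled signal; no re-referencing
  or unit inference is attempted.
* The micro-arousal rule is an explicit approximation of a visual
  judgement and is off by default.
* Only Sobel–Goodman (normal-theory) mediation inference is provided — no
  bootstrap CIs.
* Slow/fast spindle sub-bands are not split; the single 9–16 Hz band is
  analyzed (band edges are configurable).
* Missing data are handled complete-case per model; no imputation.
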