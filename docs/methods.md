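# Methods

This note records the models behind each pipeline stage, the choices made
where the procedure was genuinely open, what the synthetic generators do and
do not emulate, and the numerical conventions that affect results.

## Ratiometric trace analysis

**Model.** Each ROI yields two fluorescence series, YFP and CFP. Calcium
responses move the channels in opposite directions; multiplicative gain
processes (photobleaching, focus drift, excitation fluctuations) move them
together. The per-frame Y/C ratio therefore carries the calcium signal and
cancels shared gain to first order.

**Correction and Z-scoring.** The published correction procedure for the
Y/C ratio is cited to prior work rather than restated, so the correction
here is a documented stand-in exposed as a strategy hook: a line is fitted
to the 5-min pre-application baseline (robust Theil–Sen by default;
ordinary least squares or no detrending selectable) and subtracted from the
whole session segment, then the trace is standardised by the baseline mean
and sample SD. Over the baseline the Z trace has mean 0 and SD 1 by
construction, and the result is invariant to affine transforms of the raw
ratio. A baseline whose detrended residual SD is zero (to within 1e−10 of
the ratio scale) is rejected as degenerate rather than producing a Z trace
of amplified rounding noise.

**Windows.** All windows are half-open `[start, end)` in seconds; frame
`i` sits at `i × frame_interval`. The screening statistic is the mean Z
over `[onset, onset + 300 s)`; receptor-identification comparisons use
`[onset + 600 s, onset + 660 s)`. Indices are 0-based internally and
1-based in exported tables.

**Quartile classification.** Per-ROI mean Z-scores are pooled across
slices; quartiles use linear interpolation of order statistics at positions
`p·(n−1)` (the common inclusive convention — deterministic and the dominant
default in scientific software). Q3 > 2 classifies the substance as
increasing calcium, Q1 < −2 as decreasing; both at once is rejected as an
unclassifiable bimodal cohort; fewer than 4 values is an error. The ±2
band is deliberately conservative: pure-noise cohorts have quartiles within
a fraction of a Z unit of zero, so null substances classify as "none"
essentially always (measured in the acceptance run).

**FWHM.** The suppression duration is computed exactly as defined: the
minimum of the 120-frame moving average of Z_YC (Z_min120), then the first
and last frame at which the *raw* Z_YC is strictly below 0.5·Z_min120.
The moving average is centered and truncated at the recording edges
(symmetric bias; the convention is recorded in the result object). ROIs
whose 0–5 min mean Z is not below −2 are excluded. A transient whose first
or last crossing touches a recording boundary is flagged `censored`. Ties
cannot arise under strict inequality on floats; equal values resolve to the
first/last index by the scan itself.

Because the crossings are read from the raw Z trace, whose baseline noise
has SD 1 *by definition* of the Z-score, the first/last-passage times are
biased outward by noise regardless of how clean the recording is: on
simulated depth-8, 600-s responses the measured width overshoots by roughly
25%. The FWHM oracle tests therefore validate the statistic in two
complementary ways: exact agreement with an exhaustive threshold-scan
oracle on noisy traces (the statistic is computed correctly), and width
recovery within half the smoothing window on noiseless analytic kernels
(the statistic means what it should). The acquisition frame interval is a
required parameter throughout — the slice-imaging interval is not something
the package can assume.

**ΔR/R₀.** For stimulation experiments the raw ratio is used: R₀ is the
mean over the 30 s before stimulation onset, and peak ΔR/R₀ =
(max R − R₀)/R₀, invariant to uniform rescaling of the trace.

**Session orchestration.** Within a recording, each application is scored
against the 5 min immediately preceding its onset. A baseline truncated by
the previous application (or the recording start) flags the session; it is
still scored if at least 30 baseline samples remain, and reported as NaN
otherwise — never silently dropped.

## Tail-suspension immobility

**Model.** The body-area series of a suspended mouse is a baseline plus a
narrowband pendulum oscillation (always present) plus broadband struggling
bursts. The struggle signal TS_WLT is the time marginal of continuous
wavelet transform coefficient magnitudes over scales spanning the struggle
band only (default 2.5–10 Hz, analytic Morlet `cmor1.5-1.0`, 24 log-spaced
scales); pendulum-band scales (default 0.2–2 Hz) are excluded by
construction, so the pendulous component is subtracted out up to spectral
leakage (measured below 0.2% for a pendulum-band tone). Whether the
original analysis used a single-scale reconstruction or a band marginal is
not specified anywhere; the band marginal is used here because its
correctness is directly testable against tone inputs.

**Scoring.** σ_WLT is the population SD of the full-session TS_WLT (the
worked arithmetic example in the validation suite fixes the population
convention); frames with TS_WLT < σ_WLT/2 are immobile. The threshold
scales with the signal, so the mask is invariant under positive rescaling.
No minimum bout duration or smoothing is applied by default (none is
specified by the source procedure); the mask is exported so external manual
correction can be re-imported. Alternating mobile/immobile runs tile the
session; each mobile run pairs with the following immobile run to form an
epoch for the photometry stage.

## Vigilance staging

**Features.** Per 4-s epoch: IR activity counts summed; EMG RMS after
band-passing (acquisition band 15–300 Hz, auto-clipped below Nyquist when
left at the default; an explicitly requested band above Nyquist errors);
EEG δ (1.5–4 Hz) and θ (5–8 Hz) band RMS, with the θ ratio = θ RMS / δ RMS.
"Amplitude" is implemented as band RMS — whether the original scoring
software used RMS, peak or spectral power is not stated, and RMS is the
stable choice for 4-s windows.

**Cascade.** Rules fire in fixed order, first match wins: IR above
threshold → W; EMG above threshold → W; δ above threshold → NR; θ ratio
above its cut → R; otherwise the epoch copies the previous label (first
epoch: W, since recordings start with handling-induced wakefulness).
Thresholds are resolved per recording from feature percentiles (IR and EMG
75th, δ 60th; θ-ratio cut fixed at 1.0), all overridable with absolute
values; percentiles make the defaults robust to gain differences between
animals.

**Known limitation.** Percentile thresholds presuppose a recording that
contains a reasonable mix of states. On strongly skewed recordings (e.g. a
short recording that is 85% wake) a percentile lands inside a state's own
feature cluster and that state leaks into its neighbours; homogeneous test
vectors therefore use absolute thresholds, and recovery claims are made for
bout-structured recordings long enough for the composition to be
representative (24-h synthetic recordings stage at ≈99% accuracy, ~25-min
ones at ≥90%). Manual rescoring is represented only as a provenance flag on
imported label files.

**Durations.** Per light/dark period, state totals are label counts ×
epoch length; schedules must tile the recording with boundaries aligned to
epoch edges, so W + NR + R exactly equals the period length.

## Fiber photometry

**De-interleaving.** The 1 kHz PMT stream alternates 25-point bursts of
470-nm and 405-nm excited fluorescence (50-point cycle, 20 Hz). Burst
points 13–24 (1-based, inclusive; 12 samples) are averaged into one 20 Hz
sample per channel; points 1–12 and 25 are discarded as LED
settling/transition samples. PMT voltages are negative at the operating
point (≈ −1 V and −0.5 V); all operations are sign-agnostic.

**Isosbestic correction.** F_GC = F470 − F405·µ470/µ405 with the channel
means µ taken over the first third of the *full* recording — the formula is
defined before any behavioral windowing, and the full-recording reading is
the one implemented (the alternative, first third of the TST window only,
is the ambiguity; the choice is fixed here and configurable via the window
argument order). Components that scale both channels proportionally cancel
exactly; the generators enforce this structure, and the round-trip test
recovers the latent signal to machine precision when the latent signal
averages to zero over the first third.

**Normalization.** F_TS is a 10-point trailing (causal) moving average of
F_GC over the TST window, truncated at the start; a centered variant is
selectable. F_TSre rescales F_TS to [0, 1]. Per mobile→immobile epoch,
F_Enorm = (F − F_Emin)/(F_Emax − F_Emin) with F_Emax the mobile-period
maximum and F_Emin the immobile-period minimum; F_Eonset is F_Enorm at the
first immobile frame, averaged over valid epochs per animal. F_Enorm is
anchored — 1 at the mobile max, 0 at the immobile min — but not clamped:
samples outside those anchors can exceed [0, 1], matching the definition
rather than a clipped variant. Epochs with F_Emax ≤ F_Emin are flagged
invalid and excluded from the mean; a session with no valid epoch errors.

## Clustered statistics

**ICC.** One-way random-effects ANOVA estimator:
ICC = (MSB − MSW)/(MSB + (m̄−1)·MSW) with the unbalanced-design adjustment
m̄ = (N − Σmᵢ²/N)/(k − 1). Negative estimates are reported as-is (the
estimator's range extends below zero) but clipped to 0 when fed into the
design effect. At k = m = 20 the estimator's small negative bias keeps the
Monte-Carlo mean near 0.49 for a true ICC of 0.5.

**Effective sample size.** The plain design-effect formula
n_eff = N/(1 + (m̄−1)·ICC). The cited R implementation's internal formula
is not printed in the source literature, so exact agreement with it cannot
be asserted; the design-effect form is the canonical one and is what the
identities in the tests check (n_eff = N at ICC 0, = k at ICC 1 for
balanced designs, strictly decreasing in ICC).

**Mixed models.** Group comparisons delegate to a random-intercept linear
mixed model (statsmodels MixedLM, REML); this module owns only the
specification and bookkeeping. Confidence intervals and pairwise p-values
use a t reference with between-cluster degrees of freedom (k − number of
groups) rather than the default normal approximation, which undercovers
with few animals; on balanced two-group designs the estimator coincides
with the exact cluster-means analysis and its simulated CI coverage is
≈95%. Pairwise p-values are Holm-adjusted by default (any statsmodels
`multipletests` method is accepted); a Tukey adjustment after a mixed fit
has no statsmodels equivalent, and the difference is conservative.
Singular or non-converged fits are reported through result flags, never
masked.

## Synthetic generators: what they emulate, and what they do not

All generators are deterministic given a seed, and every output carries a
ground-truth sidecar.

**Ratiometric recordings.** Channels are
`chan0 · exp(−t/τ_bleach) · m(t) + ε` with i.i.d. additive Gaussian noise
per frame and channel (default SD 1% of the channel baseline, τ = 7200 s)
and an exact anti-correlated response split, `m = √(1+r)` for YFP and
`1/√(1+r)` for CFP, so the ratio is `R₀(1+r)` exactly and bleaching cancels
in the ratio. The response kernel is a Gaussian bump with exact analytic
FWHM (SD = FWHM/2√(2 ln 2)), peaking 0.8·FWHM after onset + delay, gated to
zero before application onset by a smoothstep that ends below the half-max
crossing — the gate keeps the pre-onset baseline clean without touching the
analytic width. Response depth is specified in Z units and converted to a
ratio amplitude using the analytic baseline ratio noise SD
(√2 · noise_sd · e^{t/τ}), so the downstream Z trace reaches ±depth by
construction; at exactly zero noise a "response in Z units" is undefined
and the Z-scoring stage correctly rejects the degenerate baseline. Defaults
(12–16 ROIs per slice, 1-s frames, 5-min baselines, 2-min applications,
depth 4 with responder fraction 0.75 for calibration cohorts) mirror the
screening design. Not emulated: imaging-plane motion, focus-adjustment
gaps, ROI overlap, and kernel asymmetry (real onset kinetics are faster
than recovery).

**Tail suspension.** Baseline area + always-on pendulum tone (0.7 Hz,
amplitude 300 px²) + band-limited (2.5–10 Hz) struggle noise of RMS 300
confined to bouts + white measurement noise of SD 60 (struggle SNR 5).
Ground-truth immobility is the bout complement. Not emulated: fiber-cable
artifacts (the situation that required manual correction in practice),
amplitude drift, bout-edge ramps.

**EEG/EMG/IR.** Pink (1/f) background EEG plus δ- and θ-band noise with
per-state gains (NR: δ 40; R: θ 28 with EMG atonia; W: EMG RMS 40 and IR
rate 10 counts/epoch; wake EEG is δ-leaning so its θ ratio stays below 1),
log-normal per-epoch gain jitter (σ = 0.25), and state sequences from a
persistent Markov chain (persistence 0.96, stationary mix ≈ 45/45/10
W/NR/R). Not emulated: spindles, artifacts, transitional epochs, circadian
modulation of band power.

**Photometry.** Steady burst values
`f470 = v470(1 + a·artifact) + gain·latent`, `f405 = v405(1 + a·artifact)`
(operating points −1 V / −0.5 V), optional LED-settling ramps on burst
points 1–12 and a transition sample at point 25 to exercise the 13–24
averaging window, optional per-point noise. The proportional artifact
structure makes the isosbestic correction exact, which is what makes the
correction *testable*; real 405-nm signals cancel motion only
approximately. The latent signal should average to zero over the first
third of the recording for exact recovery (otherwise the µ ratio absorbs
part of it — a property of the correction itself, not of the generator).

**Clustered values.** One-way random-effects draws,
value = cluster effect (variance = ICC) + residual (variance = 1 − ICC).

## Problem sizes and numerics

The validation suite runs the screening calibration at 200 cohorts per
condition (two 12-ROI slices each), the FWHM oracle on 1,000 random
1,500-frame traces, immobility recovery on 100 six-minute sessions, staging
on one 24-h recording at 200 Hz (the EMG band clipped to 15–90 Hz below
Nyquist), and the ICC Monte Carlo at 500 replicates of k = m = 20 — sizes
at which every rate estimate is stable to well under its acceptance margin.
Band-pass filters are 4th-order Butterworth applied forward-backward
(`sosfiltfilt`, zero phase). Quantiles, detrending and moving averages are
deterministic; all stochastic tests are seeded.
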