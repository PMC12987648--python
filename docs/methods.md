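# Methods

This note documents the models, parameter choices and numerical
conventions behind `c1readout`, in the order the pipeline runs.  Global
conventions: latencies in ms with time 0 at the aligning event, sample
indices 0-based, epoch windows half-open `[t0, t1)` (measurement windows
such as the 80–90 ms C1 window are endpoint-inclusive), amplitudes in µV.

## Stimulus model

Each trial presents two 9×9 contrast arrays (upper-left / lower-right
quadrant).  Grand-mean contrast is exactly 0.60; the target array mean is
`0.60 + adj` and the other `0.60 − adj`, where `adj = dc + bias` for
upper-field targets and `dc − bias` for lower-field targets.  The bias
term counteracts response bias by making the task asymmetrically harder;
applying it antisymmetrically preserves the 60% grand mean exactly on
every trial, which is why that reading was adopted.  Within each array a
fixed multiset of deviations (±0.20 in 0.05 steps, each value nine times)
is arranged so that every grid column holds a full shuffled copy; the
deviations sum exactly to zero, so differential contrast never varies
across trials.  These conservation laws are exact, not approximate, and
are asserted as such in the tests.

## Observer model

No closed-form observer accompanies the analysis being re-implemented, so
the generator uses the simplest mechanism that reproduces all of the
behavioural regularities at once — a two-stage bounded accumulator:

| parameter | default | meaning |
|---|---|---|
| `early_latency` | 80 ms | arrival of the transient early sensory sample |
| `early_gain` | 6 /contrast | weight of the early sample |
| `early_noise_sd` | 0.5 | sd of the early sample (shared with C1) |
| `late_latency` | 150 ms | start of sustained evidence-dependent drift |
| `late_gain` | 25 /s/contrast | drift rate per unit contrast difference |
| `late_noise_sd` | 0.6 /√s | accumulator diffusion |
| `start_sd` | 0.40 | start-point variability (fast guesses) |
| `bound` | 1.0 | decision threshold |
| `urgency_slope` | 1.25 | bound reaches 0 at `deadline/urgency_slope` |
| `motor_delay_mean/sd` | 110 / 18 ms | Gaussian motor delay |
| `history_bias` | 0.25 | start-point push toward switching |

The collapsing bound guarantees a response on every trial and yields the
qualitative structure the analyses need: the fastest responses are
start-noise-driven (chance accuracy, switching bias expressed), accuracy
rises once the early sample and drift dominate, and falls again at slow
RTs where the collapsing bound forces decisions on ambiguous evidence —
a concave conditional-accuracy function.  The shorter deadline truncates
accumulation earlier, giving lower accuracy and faster, less variable
RTs.  The noise scales were fixed once so that, at a titrated DC, median
RTs fall near 270/330 ms under the 400/600 ms deadlines; they were not
revisited afterwards.

Single-trial C1 amplitude is generated as
`c1 = −c1_gain·Δc − shared_noise_gain·ε_early + N(0, c1_noise_sd)`,
where `Δc` is the signed upper-minus-lower contrast difference and
`ε_early` the early-sample noise.  Positive values mean lower-field-like
activity; noise pushing the *choice* toward "upper" makes the C1 more
negative, which is the choice-congruent direction.  Setting
`shared_noise_gain = 0` severs the C1–choice link without changing either
marginal — the null configuration used in calibration tests.

`titrate_difficulty` automates the experimenter's loop: simulated blocks
(default 120 trials), multiplicative Robbins–Monro DC steps against the
accuracy error with a decaying rate, additive bias steps against choice
imbalance.  The returned calibration is the Polyak average (geometric
mean of DC) over the latter half of a fixed-length trajectory: log-DC
oscillates around the solution there, and averaging avoids both
single-block noise and the upward bias a stop-at-first-hit rule inherits
from approaching the target from the easy side.  Validation accuracy at
the returned calibration lands within ~1–3 points of the 55% target
across seeds.  Block score: 10 points per correct timely response, −7
otherwise.

## Forward model and EEG

A deterministic 128-channel concentric-ring cap (labels A1…D32) supplies
2-D positions; rings fill from the back alternately left/right so reduced
montages keep symmetric posterior coverage.  Real geometry is not needed
by any stage.  Component topographies are unit-norm Gaussians over these
positions:

* **C1**: each field's response is dipolar (main posterior-midline lobe
  plus an opposite-sign counter-lobe nearer the occipital rim), with the
  upper field negative-going — so the upper-minus-lower difference
  topography has two posterior poles, which is what the bipolar
  measurement exploits.  The transient is a raised cosine spanning
  70–100 ms.
* **CPP**: centroparietal ramp from `late_latency` to the response
  (then exponential decay), slope `cpp_gain·(cpp_base + |Δc|)` with
  `cpp_gain = 100 µV/s` and an evidence-independent base of 0.25 —
  accumulation starts regardless of evidence; evidence steepens it.
* **Alpha**: 10 Hz pre-target oscillation, amplitude
  `alpha_base − alpha_gain·[chosen side contralateral]`, fading within
  150 ms of target onset.
* **Noise**: EEG-like background — 1/f with a ~1 Hz knee, a broad alpha
  bump, steeper rolloff above 15 Hz — split into an independent
  per-channel part (40% variance), a spatially global part (30%) and
  three smooth random spatial patterns (30%).  The structured parts mimic
  volume conduction: they are what average referencing and bipolar
  derivations cancel.  Single-trial C1 measurements on this background
  correlate only ~0.1 with the generated amplitudes, which is the
  realistic regime — the analyses derive their power from trial counts.
* **Artifacts** (optional, with ground-truth labels): blink pulses on the
  vEOG trace with a frontal scalp spill, low-frequency drift sinusoids
  and 25–38 Hz muscle bursts on random channels.

What the generator does **not** emulate: realistic head-model mixing,
eye-movement traces (gaze enters as per-trial summaries), learning or
fatigue, inter-participant topography variability, and any dependence of
noise on task state.  Passing recovery tests therefore demonstrate that
the estimators work when their assumptions hold, not that real data meet
those assumptions.

Two reduced ground-truth generators exist for estimator validation:
`simulate_c1_dataset` injects a choice-congruent C1 component of known
size only on trials inside a given RT band (behaviour still comes from
the accumulator), and `simulate_cpp_divergence_dataset` builds
single-channel waveforms whose easy/hard slopes separate at exactly
150 ms post-stimulus, with one shared RT distribution (mean 330, sd
25 ms, noise 3 µV).  The RT dispersion matters: the response-locked
divergence point is smeared by RT variability, and the modest sd keeps
the estimator's detection point aligned with the true divergence time;
at realistic RT spreads the estimate inherits a bias of a few tens of
ms, a known limitation of the response-locked approach.

## Preprocessing

**Filter.**  The anti-aliasing low-pass is a symmetric 77-tap
Hanning-windowed sinc (`w[n] = 0.5(1 − cos 2πn/(N−1))`), unit DC gain,
applied by centred convolution so group delay is compensated.  The
nominal cutoff is recovered from the published response figures rather
than assumed: a filter this short cannot reach ~80 dB of generic
stop-band rejection, so the quoted 83.5 dB at 50 Hz is only attainable on
the flank of a stop-band null placed at the mains frequency.  The cutoff
is grid-searched (0.01 Hz steps, root-refined) for the attenuation match
on the null branch whose −3 dB corner lies nearest the quoted corner;
the recovered design (cutoff 38.72 Hz) shows exactly 83.5 dB at 50 Hz
with a corner of 35.8 Hz.

**Epochs.**  Half-open spans at 512 Hz: −600…400 ms target-locked epochs
are exactly 512 samples; −600…100 ms response-locked epochs are 358.
Baseline −50…30 ms (inclusive), subtracted per trial and channel;
idempotent.

**Screening.**  Blinks: |vEOG| > 40 µV, contiguous violation runs padded
±50 ms; a blink overlapping stimulus presentation (0–39 ms), a saccade,
or median gaze deviation > 1° within ±100 ms of onset rejects the whole
trial.  Drift: (0–3 Hz)/(3–7 Hz) periodogram power ratio > 5; muscle:
(20–40)/(3–7) > 2; absolute 50 µV; baseline range 40 µV.  Band powers
use a single-taper (rectangular) periodogram over the whole epoch, bins
half-open, and the DC bin is always excluded — baseline-corrected epochs
carry an arbitrary mean offset that is not oscillatory content.  Power
(not amplitude) spectra are used.  Channel-level flags exclude only that
channel's overlapping samples; noisy channels can alternatively be
rebuilt by inverse-distance-weighted interpolation of the four nearest
montage neighbours (a documented simple scheme; spherical splines are out
of scope).  Trials with RT > 600 ms are excluded at the analysis layer.

## Feature extraction

C1 electrodes come from the easy block: average 80–90 ms per target
location, subtract, and take the `k = 4` most positive and most negative
electrodes (configurable; the count is not dictated by anything) within
the posterior pool (montage positions below the horizontal midline).
Absence of sign-opposed poles raises a dedicated error — the analogue of
excluding a participant without an identifiable C1.  The single-trial
measure is mean(positive pole) − mean(negative pole) over 80–90 ms;
fully flagged windows yield missing values, never errors.

The STFT uses a rectangular taper, 400 ms windows (205 samples at
512 Hz) hopped at 25 ms, magnitudes divided by half the window length so
a sinusoid at a bin frequency reads out its amplitude; analysis
frequencies are all non-zero bins ≤ 30 Hz (twelve at 512 Hz).

The choice-signal search operationalises visual inspection liberally:
group t-tests of per-participant upper-chosen minus lower-chosen
averages, candidate clusters contiguous in time (≥ 20 ms, ≥ 2
electrodes) at uncorrected p < 0.05, positive and negative deflections
clustered separately (a lateralised effect must not cancel within one
candidate), adjacent frequencies merged when time-window and electrode
Jaccard overlaps are ≥ 0.5, retention by a group t-test on the cluster
mean.  False positives are acceptable by design: candidates become
control covariates.

## Choice models

Coding: upper-field targets/choices, correct responses and the 600 ms
deadline are 1; their complements 0.  Continuous predictors are z-scored
over the included trials pooled across participants (configurable);
RT enters in seconds, uncentred.  Each predictor contributes main,
linear-RT and quadratic-RT columns (16 predictors → 48 regressors plus
intercepts).  Missing covariates are deleted listwise per model.

The logistic core is an in-package Newton/IRLS fitter (needed because the
window and bootstrap loops perform tens of thousands of fits); it is
cross-checked against independent maximum-likelihood fits to 1e−6 in the
tests.  Random intercepts are marginalised by a Laplace approximation:
joint penalised IRLS for the mode of (β, u), profile optimisation of the
intercept variance on the Laplace marginal likelihood.  The sliding
window models omit random intercepts (extreme windows have unbalanced
per-participant counts and the pooled results are not qualitatively
different); α = 0.05 two-sided Wald tests throughout; Wald t is referred
to a t distribution on residual degrees of freedom.

Sliding windows: 81 centres at unit percentiles 10–90 of the pooled
included-trial RT distribution, each window spanning 20 percentile
points.  The reported C1 coefficient is sign-flipped so positive means
choice-congruent; run fitting and zero-crossing interpolation use the raw
series (the flip changes neither).  Collinearity pruning greedily removes
the regressor involved in the most violating pairs (ties by largest
|r|) until all pairwise |r| ≤ 0.5, never touching protected columns; an
unsatisfiable request (e.g. protecting uncentred `x:rt` and `x:rt2`
together, which correlate at ~0.96 by construction) raises an error
naming the blocking pair rather than silently relaxing.

## Onset estimation

The per-window significance sequence is modelled as one unbroken
significant run with non-significant windows outside; the fitter
maximises agreement between implied and observed flags by exhaustive
search over the O(n²) runs (n = 81), the empty run competing on equal
footing.  Ties prefer the longest run, then the earliest start — a
deterministic rule chosen for contiguity; nothing hangs on it in
practice, but it is pinned by tests against brute force.  Run edges are
converted to latencies by linear interpolation of the coefficient's zero
crossing in the adjacent gap, falling back to the edge window centre when
no crossing exists.

Bootstrap: participants resampled with replacement (trials intact
within a participant), the full window series rebuilt per sample, medians
and 2.5/97.5 percentile CIs over samples; empty-run samples contribute no
latencies and are counted, not imputed.  Default 10,000 samples at study
scale; validation and test configurations use 500 (documented problem
size, chosen so the full suite stays interactive).  Above-chance-accuracy
onsets use an intercept-only logistic model per window (significant =
p < 0.05 and above chance); paired evaluation of two window models on
identical samples yields difference CIs.

## CPP onset

Response-locked epochs span −600…100 ms; the pre-stimulus baseline is
subtracted before response-locking.  The measurement electrode is the
centroparietal-pool channel with maximal mean amplitude in −150…−50 ms
(ties to the first in the pool).  Slopes: OLS line fits in 50 ms windows
stepped 10 ms on per-participant condition-average waveforms; paired
one-sided t (easy > hard) per window.  Onset = the earliest window that
is significant and stays significant through the last window lying wholly
before the easy-condition grand-average peak — windows overlapping the
peak are exempt, because buildup rate passes through zero at the peak by
definition.  Stimulus-locked conversion subtracts the absolute
response-locked onset from mean RT; the pooled estimate averages the
all-trials, fast-half and slow-half medians.

## Decoding

Per 10 ms window, per participant: LDA (least-squares solver, Ledoit–Wolf
shrinkage, because 128 channels with few trials make the sample
covariance singular) trained and evaluated on the same trials, matching
the protocol being emulated; chance is the mean accuracy over 100
label-shuffled refits of the same features, and the group comparison is a
paired test of real vs shuffled per window.  Train-equals-test accuracy
is optimistically biased by construction — that is precisely why chance
is estimated empirically rather than assumed to be 0.5.

## Known limitations

* The observer is a phenomenological stand-in: it reproduces the
  behavioural regularities but is not fitted to any data, and its
  parameters are not identifiable claims about mechanism.
* The response-locked CPP onset estimator is biased under large RT
  dispersion (divergence smearing); the validation generator keeps
  dispersion modest, and the pooled estimate is the stable quantity.
* The significance-run onset inherits half-window blurring from the
  20-percentile window width; recovered band edges are accurate only to
  about one window width.
* The liberal signal search is intentionally anticonservative and its
  output should never be interpreted as evidence of real signals — only
  as covariates to control for.
* The simplified montage and Gaussian topographies support electrode
  selection logic, not source-level claims; spherical-spline
  interpolation is replaced by an inverse-distance scheme.
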