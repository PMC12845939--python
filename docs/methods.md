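# Methods

This note documents the models behind `oculogate`, the parameters that
matter, the synthetic-data design, and the numerical choices — in enough
detail to judge what the test suite does and does not demonstrate.

## The screening problem

The system gates access to a vehicle on two eye-camera measurements taken
before driving: biometric identity (iris code) and a physiological screen
for a depressive response pattern.  Screening is *individual-baseline
relative*: every feature is z-scored against the person's own reference
distribution collected across rested, tired and stressed states, so the
decision depends on how a person deviates from themselves, not on population
norms.  The screen is an early-warning flag, not a diagnosis.

## Iris module

**Segmentation.**  Pupil and limbus circles are found with the
integro-differential operator: maximise over centre and radius the blurred
radial derivative of the normalised circular line integral of intensity,
pupil first, then limbus constrained to a radius at least 1.2× larger.  The
coarse centre comes from the centroid of the darkest intensity decile.  On
the synthetic renders this recovers centres within 1 px and radii within
2 px of ground truth.  Real deployments segment with a learned model; the
segmentation interface is a single function and is pluggable.

**Normalisation.**  Homogeneous rubber-sheet mapping: sample the image at
`p(θ, ρ) = (1−ρ)·p_pupil(θ) + ρ·p_limbus(θ)` on an `n_radial × n_angular`
grid (16×16 for 512-bit codes, 16×32 for 1024-bit), bilinear interpolation.
Because the generator paints the iris texture in the same normalised
coordinates, the mapping is dilation-invariant by construction (measured
texture correlation > 0.9 between 10% and 40% dilation renders of one
identity).  An `angular_offset` argument rotates the sampling grid by whole
angular steps; this is exactly a circular column shift of the texture,
whereas a physically rotated *render* matches its shifted counterpart only
up to bilinear pixelation (correlation ≈ 0.9 at 16 angular samples).

**Encoding.**  Each radial row is mean-subtracted and filtered along the
angular axis with a one-sided log-Gabor transfer function
`G(f) = exp(−ln²(f/f₀) / (2 ln² σ))`, centre frequency `f₀ =
max(2, 3/16 · n_angular)` cycles, bandwidth ratio σ = 0.5; the inverse FFT
of the one-sided spectrum gives the analytic (complex) response, and each
sample quantises to two bits: sign of the real part, sign of the imaginary
part.  Phase bits of independent textures are Bernoulli(1/2), so impostor
comparisons concentrate at Hamming distance 0.5 (measured 0.505 ± 0.005 over
100 pairs without shift search).

**Matching.**  Fractional Hamming distance minimised over circular angular
shifts of ±4 positions (one position = 2 bits); acceptance threshold 0.32, a
classical operating point, configurable.  No occlusion mask bits are used —
the synthetic images have no lids or lashes — but the code container leaves
room for one.

**Evaluation.**  `FAR(t)` = fraction of impostor scores ≤ t, `FRR(t)` =
fraction of genuine scores > t, `GAR = 1 − FRR`; the EER is read at the
FAR = FRR crossing by linear interpolation on the sign-change segment of
`FAR − FRR`.  The packaged verification experiment enrols 100 identities
through the full image pipeline and scores 5 acquisition samples per
identity (8% independent bit perturbation + rotation jitter uniform within
±4 positions) against their templates, plus ≥ 10⁴ random impostor pairs.
Samples are scored against the enrolled template rather than against each
other because two samples may differ by up to twice the jitter bound, which
would exceed the shift search by construction.  Measured EER: 0.0% at this
problem size — the genuine (≈ 0.08) and impostor (≈ 0.46 after shift-search
minimisation) distributions do not overlap.

## Pupillometry and gaze features

**Trace hygiene.**  Pupil samples outside 1.5–9 mm or flagged invalid count
as blinks; gaps ≤ 500 ms are linearly interpolated, longer gaps stay
invalid; the pupil is smoothed with a centred 100 ms moving average; gaze
speed comes from central differences with 20 ms smoothing.

**Per-stimulus features** (block = 5 s baseline, 8 s stimulus, 5 s rest;
baseline window = last 3 s before onset, the first 2 s treated as settling;
search window = onset to onset + 10 s to catch late peaks):

* **PDA** — signed extremal deviation of the smoothed diameter from the
  baseline mean B, as % of B.  The signed extremum (not the maximum) is used
  so a blunted/constriction response to positive stimuli comes out negative,
  matching how such responses are reported.
* **CL** — response delay.  The raw event is the last up-crossing of
  `B + 1·SD(baseline)` before the peak (anchoring to the main response makes
  the estimate robust to isolated pre-response noise excursions).  Because
  the canonical pupil impulse response has a slow foot, the crossing lags
  the true onset by a deterministic rise interval; CL subtracts it by
  solving `h(x) = φ` for the unit-peak gamma kernel, where `φ` is the
  threshold as a fraction of the observed peak.  This recovers a simulated
  400 ms latency within ±50 ms at realistic noise; a plain crossing time
  would be biased late by 250–300 ms.  CL is censored (reported missing)
  when the pupil never clears the threshold.
* **PDV** — maximum derivative of the percent-change signal, %/s.
* **FD / SV / SA** — mean fixation duration, mean saccade peak velocity and
  amplitude from an I-VT event parser (velocity threshold 30°/s, minimum
  fixation 50 ms, minimum saccade 10 ms — standard values; sub-threshold
  fragments merged).
* **GDE** — Shannon entropy (bits) of valid gaze samples on an 8×8
  equal-area grid over the display extent (default ±20° × ±12°); range 0–6
  bits, sample-based rather than fixation-based.
* **EMA** — `|ΔL − ΔR| / max(ε, (ΔL + ΔR)/2)` on absolute per-eye pupil
  dilation (mm); missing for single-eye sessions.  No standard definition
  exists for this index; this relative-difference construction is the
  package's own.

**Baseline profiles.**  Per-feature mean and SD over reference observations
from ≥ 3 sessions covering ≥ 2 states, SD floored at
`max(0.05·|mean|, per-feature ε)` so over-consistent references cannot
produce unbounded z-scores.  The screening pipeline feeds the profile one
observation per reference *stimulus* (18 per participant), not per-session
means: z-scores of single screening stimuli must be scaled by per-stimulus
variability, and a session-mean SD would understate it by ≈ √6 and inflate
false alarms accordingly.  `build_baseline` itself is agnostic to what an
"observation" is.

## Screening rules and models

**2-SD rule.**  Per stimulus, a core feature (PDA, PDV, FD) is deviant when
its direction-gated z-score is ≥ 2 (inclusive); directions encode the
depressive asymmetry: + for PDA/PDV on negative stimuli, − on positive
stimuli, + for FD on both.  A stimulus is flagged under the configurable
mode `any` / `majority` (default, ≥ 2 of 3) / `all`; a participant is
labelled depressive-pattern when ≥ 3 of their 6 stimuli are flagged.  The
majority default sits between the two readings of "deviated in the main
features", both of which remain available.

**Logistic model.**  Maximum-likelihood fit (statsmodels IRLS) with
intercept; reports per-coefficient SEs, the likelihood-ratio χ² against the
intercept-only model, and Nagelkerke's
`R² = [1 − e^{(2/n)(ll₀−ll₁)}] / [1 − e^{(2/n) ll₀}]`.  Perfect or
quasi-separation raises a dedicated error suggesting a penalised fit rather
than returning divergent estimates.  Slopes can be frozen at user-supplied
values with only the intercept estimated — useful because published models
sometimes report slopes without an intercept.  Odds ratios are `e^β`.

**Evaluation.**  Confusion-matrix metrics with NaN (not exceptions) for
zero-denominator ratios; threshold sweep with the inclusive rule
`p ≥ t ⇒ positive`; ROC/AUC via scikit-learn with the trapezoid rule (the
suite verifies AUC ≡ Mann-Whitney U / (n₁n₀)); two-sample comparisons with
the pooled-variance t-test (df = n₁+n₂−2), Cohen's d (pooled SD, sign
following mean(a) − mean(b)), Mann-Whitney U, and Shapiro-Wilk normality
screening.  No multiple-testing correction is applied (α = 0.05).

**Sequence classifier (optional).**  A conv-recurrent network (three 1-D
conv blocks 16/32/64, kernel 7, stride 2, batch-norm + ReLU; two stacked
128-unit LSTM layers; softmax head) over 2-channel derived-signal windows —
pupil %-change and gaze speed, 13 s per stimulus — trained with Adam
(lr 2·10⁻⁴), batch 32, ≤ 60 epochs, early stopping with patience 10 on a
participant-level 70/15/15 split.  Windows are derived signals, not raw
video: the screening features themselves are time series and the derived
reading keeps the input content aligned with the rest of the package.
Window construction and participant-level aggregation (mean of per-stimulus
probabilities) are plain numpy; training requires the optional `torch`
extra and is not exercised by the default test suite.

**Decision fusion.**  (identity accepted, pattern flagged) → GRANT /
DENY_TEMP_SCREEN / DENY_IDENTITY / DENY_BOTH; screening is skipped and
recorded as not-run when identification fails, and screening alone can
never grant.  Decisions append to a JSON-lines audit log.

## Stimulus corpus

Items rated 1–9 by ≥ 2 raters on valence and arousal.  Exclusions run
first: rater range > 2 scale points on either dimension, then arousal mean
≤ 2 or ≥ 8 (inclusive); survivors are negative when the valence mean ≤ 3.5,
positive when ≥ 6.5, excluded as neutral in between.  Inter-rater
reliability is ICC(2,1) — two-way random effects, absolute agreement,
single measure — computed from the ANOVA mean squares
`(MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n)`; the form is fixed but
checked against both an independent variance-components oracle and
pingouin.  Session selection draws 3 positive + 3 negative unseen items
uniformly without replacement, erroring by name on an exhausted class.

## Synthetic-data design

The generator's defaults *are* the study conditions: 242 participants with
81 (33.5%) in the depressed-pattern group; group feature contrasts
PDA_neg 18.4±6.7 vs 27.9±8.3 %, PDA_pos 6.2±4.1 vs −1.3±5.0 %, FD 280±40 vs
345±52 ms, SV 320±45 vs 276±51 °/s; 100 Hz sampling (valid range 90–120);
5/8/5 s blocks; 3 positive + 3 negative stimuli per screening session; three
reference sessions (rested/tired/stressed).  Features without published
group distributions (PDV, SA, GDE, EMA, CL) carry declared defaults chosen
once at plausible physiological magnitudes (e.g. GDE 4.2±0.6 vs 3.6±0.7
bits — more concentrated gaze under depression; PDV_neg 12±4 vs 17±5 %/s).

**Correlation structure.**  Latent per-participant feature means share a
single severity axis: `x_j = μ_gj + σ_gj · s_j (√ρ·z₀ + √(1−ρ)·z_j)` with
ρ = 0.25, where `s_j` is the direction of the depression effect on feature
j.  Features thus correlate at ρ along their effect directions — a
participant who over-responds to negative news also under-responds to
positive news.  This choice is what makes the four printed contrasts yield
a combined Mahalanobis discriminability of Δ² ≈ 4.3 and a Bayes-level AUC
near 0.93, matching the reported model discrimination; with raw-unit
positive correlation the same contrasts would imply AUC ≥ 0.97 regardless
of ρ.

**Within-participant structure.**  Per-stimulus values add noise at 30% of
the between-participant SD (the fraction is a declared choice; no published
value exists).  Reference sessions draw around the participant's *control
quantile* (same severity score mapped through the control distribution), so
depressed participants deviate from their own neutral baseline — the
mechanism the screening rule exploits.  State labels (rested/tired/
stressed) do not shift the reference distributions; fatigue/stress effects
on the features are not modelled.

**Traces.**  Pupil responses use the standard pupillometry impulse kernel
`h(t) = (t/t_max)ⁿ e^{n(1−t/t_max)}` with n = 10.1, t_max = 930 ms, unit
peak, scaled by the per-stimulus amplitude, plus Gaussian noise and
Poisson-scheduled blink gaps.  Gaze alternates fixations (Gaussian
durations, floor 50 ms; Gaussian target scatter) and saccades following the
saturating main sequence `v_peak = v_max(1 − e^{−A/a₀})` (v_max 500 °/s,
a₀ 12°) with a raised-cosine velocity profile.  Eye images place concentric
pupil/limbus circles (limbus 100 px; pupil 40·(1+dilation) px, dilation
10–40%) with an identity-seeded band-limited annulus texture painted in
normalised polar coordinates, plus acquisition noise and optional rotation.

**What the synthetic data does not emulate** — and therefore what passing
tests do *not* show about real recordings: luminance-driven pupil dynamics
(illumination is constant by protocol), eyelid/lash occlusion and off-axis
iris distortion, head pose, state-dependent baselines, habituation across
stimuli, and any link between iris identity and group membership.  The
biometric EER of 0.0% in particular reflects clean synthetic geometry; it
demonstrates the matching machinery and threshold logic, not field
performance.

## Benchmark protocols and problem sizes

* Verification: 100 identities × 5 samples, 512-bit codes, ≥ 10⁴ impostor
  pairs, 5 seeds (~20 s total).
* Discrimination: default cohort per seed, logistic on participant-level
  latent features (PDA_neg, PDA_pos, FD, SV), 70/15/15 participant split
  with the idle validation share folded into training, test share untouched,
  25 seeds.  Mean test AUC ≈ 0.92–0.93 with a per-seed SD of ≈ 0.06, almost
  all of it sampling noise of the ~36-participant test sets.
* Rule screening: one default cohort end-to-end (baseline profiles from 18
  reference stimuli per participant); typical outcome sensitivity ≈ 0.84,
  specificity ≈ 1.0.

## Numerical choices and degenerate inputs

Time is integer-friendly milliseconds with half-open windows `[start, end)`;
z and probability comparisons are inclusive (≥) per the "at least" wording
of the rules; identification ties break on the lowest gallery index; EER
interpolation is linear on the FAR−FRR sign-change segment, with the curve
endpoints used when no crossing exists; flat images raise a detection error;
empty score sets, single-class label vectors and sub-minimum reference
sessions raise errors naming the shortfall; zero-denominator metrics are
NaN; the equicorrelation parameter is validated to [0, 1).  All generators
are pure functions of (config, seed), with substreams derived per component
from a single root seed.

## Known limitations

The asymmetry index and the rule-mode reading are declared constructions
where no standard exists; the sequence classifier is untrained in the
default environment; synthetic iris images make segmentation nearly ideal,
so boundary-fit tolerances (1–2 px) say nothing about photographic inputs;
and the screening rule's near-perfect specificity on synthetic cohorts
reflects exact distributional match between reference and screening noise,
which real sessions will not provide.
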