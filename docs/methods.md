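# Methods

## The model

Multi-muscle EMG of standing up and sitting down is represented by muscle
synergies: low-dimensional modules combining an activation time course with a
vector of relative muscle contributions. Two factorizations of the same
trials are compared.

**Temporal synergies.** All trials of one movement strategy (within a
movement x floor task) are horizontally concatenated into a nonnegative
matrix `M ∈ R^{101 x 30·tr}` (101 time-normalized samples, 30 muscles, tr
trials). NMF decomposes it as

    M^s(t) ≈ Σ_n C_n(t) · W^s_n ,

with trial-independent activation profiles `C_n` (101 samples) and
trial-dependent muscle weightings `W^s_n` (1 x 30 per trial).

**Spatial synergies.** The transposed arrangement `M_spatial ∈ R^{30 x
101·tr}` yields trial-independent weighting vectors (30 x 1) and
trial-dependent activation profiles.

NMF minimizes squared (Frobenius) reconstruction error by Lee–Seung
multiplicative updates. Defaults: 50 random nonnegative initializations per
factorization, 3 000 iterations maximum, early stop when the relative
objective decrease over 10 iterations falls below 1e-6. The best restart by
final objective is kept. Temporal profiles (and spatial weighting vectors)
are stored unit-maximum with the scale folded into the counterpart factor,
so widths and weightings are comparable across models.

**Model order.** A fivefold cross-validation (folds are whole trials,
stratified by support condition) produces `R²_CV(n)` for n = 1..30, where
`R² = 1 − SSE/SST` with SST taken about the per-row mean vector (the
multivariate convention; a grand-mean variant is available behind
`sst_mode`). Two selectors operate on the across-fold mean curve:

* *R²-knee*: straight lines are fitted to the curve on intervals [k, 30],
  iteratively discarding the smallest order; the knee is the first k whose
  fit has mean squared residual < 1e-4. Because a two-point interval fits
  exactly, the search always terminates.
* *N\**: the smallest n with `R²(n) ≥ 0.9` and `R²(n) − R²(n−1) < 0.05`,
  with `R²(0)` defined as 0 (so a curve that is flat and high from n = 1
  selects n = 2 — the jump from the defined zero fails the local criterion
  at n = 1).

**Compactness.** With T = 101 samples and M = 30 muscles, a temporal model
of order n costs T·n trial-independent plus n·M per-trial parameters; a
spatial model n·M plus T·n. The package tabulates these counts and the mean
± sample SD of (spatial − temporal) selected orders across datasets.

**Matching.** Unit-maximum temporal profiles of all strategies in one task
are clustered with k-means++ (Euclidean metric, 50 restarts, 1 000
iterations). k grows from 1 until (1) every profile correlates ≥ 0.9
(Pearson) with its centroid and (2) no cluster holds two profiles of the
same strategy. Singletons are strategy-specific synergies. Clusters are
ordered by centroid peak (ties: earlier ascending half-maximum crossing),
and the clustering is repeated ten times; partition agreement across repeat
pairs (after label-free set comparison) is reported.

**Timing.** Activation duration is the full width at half maximum of a
profile's main peak, in % of the time-normalized cycle (one inter-sample
step = 1 %). Crossings are found walking contiguously outward from the peak
and interpolated linearly between samples, so secondary bumps never extend
the width. A peak whose half-height is not reached before sample 0 (after
sample 100) is a boundary synergy, measured one-sided from the start (to the
end). A constant-positive profile has no crossings: width 100 with both
boundary flags and a warning.

**Support statistics.** Per synergy, the 30-channel weighting vectors are
reduced to 16 responses (left/right means of the 14 bilateral muscles, plus
erector spinae and rectus abdominis; rectus abdominis last as the reference
level), stacked across trials and muscles, and fitted by maximum likelihood
as a linear mixed model with a participant random intercept:

    stage 1:  weighting ~ LT + FS + (1 | participant)

run twice (unassisted and light-touch reference, dummy coding) so all
pairwise support contrasts are tested; Bonferroni over 2 x n_synergies tests
per strategy. If stage 1 is significant the interaction model

    stage 2:  weighting ~ (LT + FS) * muscle + (1 | participant)

is fitted with the muscle factor effect-coded (rectus abdominis omitted), at
most three follow-up tests (alpha/3). Wald t statistics use residual degrees
of freedom (observations minus fixed-effect rank); statsmodels MixedLM is
the estimation backend. The stacked-response formulation implies a single
residual variance shared across muscles; per-muscle residual variances are a
known limitation of this reading. Residual diagnostics (skewness, omnibus
normality, Spearman |residual|-vs-fitted) are advisory only.

## EMG preprocessing

Raw EMG (two acquisition systems, 1 500 and 4 000 Hz; each channel processed
at its native rate) is band-pass filtered 20–500 Hz and notch filtered at
50 Hz with 4th-order zero-lag Butterworth filters. The forward-backward
passes are padded with the whole signal (odd extension): the Q = 30 notch
rings for ~0.2 s, and short default padding leaves edge transients that also
break the time-reversal symmetry of zero-lag filtering.

ECG artifacts on the trunk channels are removed by template matching: beats
are detected per channel on a 50 ms-smoothed absolute trace (threshold
median + 3.5 robust SD, 0.3 s refractory period), the template is the mean
of ±60 ms beat-aligned windows across all of a participant's recordings
(≥ 30 s of signal and ≥ 10 beats required, both configurable), and at each
beat the template is subtracted after per-beat least-squares scaling. Beats
too close to a signal edge are skipped.

Envelopes are full-wave rectified and low-pass filtered at 10 Hz (4th-order,
zero-lag), clipped at zero (the low-pass can undershoot and NMF requires
nonnegativity).

Movement events come from 3-phase k-means++ clustering of standardized
features on a common 100 Hz grid: vertical GRF, seat force, CoM height and
CoM vertical velocity, all conditioned with a 10 Hz zero-lag low-pass. The
velocity feature is up-weighted (x2) because it alone separates the moving
phase from both static phases; without it the phase boundary lands mid-rise.
Labels are mode-smoothed (150 ms window); the largest contiguous run of the
middle phase bounds the movement; the seat transition is where the seat
force crosses 2 % of the sitting seat load (configurable) inside that
window. Detection on the synthetic cohort recovers true events within
±0.1 s. Trials are segmented from 200 ms before movement start to movement
end, cubic-spline resampled per channel to 101 points, and
amplitude-normalized per muscle and participant to the maximum across that
participant's trials (identically-zero muscles are left unscaled and
flagged). Trials marked as having corrupt channels are excluded before
normalization.

## The synthetic cohort generator

No public recordings accompany the study design this package targets, so
every downstream stage is validated against a generator with known ground
truth. Per task-strategy the generator owns:

* unit-maximum truncated-Gaussian activation profiles on the 0–100 % grid.
  Default peaks spread evenly; the width parameter grows linearly from σ = 4
  (% of cycle) at mid-cycle to σ = 10 at the boundaries, so seat-transition
  synergies are briefer than boundary synergies — the timing structure
  observed in standing up and sitting down. Gaussian bumps keep the FWHM
  analytically known (2√(2 ln 2)·σ).
* baseline muscle weightings drawn from gamma(2) per channel, sparsified
  (25 % zeroed, two private channels per synergy that no other synergy
  loads) and group-structured: mid-cycle synergies weight the lower limbs
  x4 (leg extension), boundary synergies the upper body x4 and trunk x2
  (stabilization, arm use). Sparsity/privacy makes the planted factorization
  separable — without it exact NMF reconstructions exist whose factors do
  not match the planted ones, and recovery tests would be meaningless.
  Group dominance mirrors real synergy physiology and gives each synergy a
  nonzero net response shift under support, which the stage-1 model (a test
  of the common shift across muscles) can detect; with group-neutral random
  weightings the planted redistribution cancels out of the stacked mean by
  construction.
* support effects as multiplicative muscle-group factors (defaults:
  unassisted 1/1/1; light touch 1.15 upper, 0.95 lower; full support 1.6
  upper, 0.6 lower — load transfer from legs to arms, with the arm increase
  outweighing the leg decrease so a net shift exists). Trial weightings are
  baseline x factors x mean-one lognormal jitter (σ = 0.2), so planted
  FS/UA group ratios survive averaging.
* envelope noise: additive zero-mean Gaussian (σ = 0.05 on the unit-max
  scale), clipped at zero.

Raw-signal trials modulate band-limited (20–450 Hz) unit-RMS noise carriers
with the envelope mapped onto wall-clock time between the configured events
(defaults: start 1.0 s, seat transition 1.5 s, end 2.4 s, 3.2 s total; a
resting tone of 0.08 outside the movement), add 50 Hz hum (0.05) and, on the
trunk channels, a Ricker-wavelet ECG artifact train (amplitude 4 x carrier
RMS, 1.2 Hz, random phase). Kinetic traces are phenomenological templates:
seat force follows a smoothstep reaching zero exactly at seat-off (reverse
for seat-on), vertical GRF is body weight minus seat force plus an inertial
transient, and the CoM follows a trapezoidal-velocity path between the
events. The physical magnitudes (per-muscle activation, SNR) are free
parameters chosen once as plausible, not calibrated to any recording.

Randomness: one master generator per cohort seed draws a child seed per
trial in a fixed traversal order, so cohorts are bit-reproducible and trials
independent. Per default, strategy assignment is fixed per participant x
floor x movement (drawn seeded from the task's strategy list); a
probabilistic per-trial rule is available.

### What the generator does not emulate

Electrode lift-off and motion artifacts, muscle-specific spectral shapes,
fatigue, crosstalk between channels, kinematic variability of event timing
across trials (events are fixed per cohort), and any genuine biomechanics —
kinetic traces are templates, not forward dynamics. Passing tests therefore
show the pipeline recovers what it is designed to recover under its own
noise model; they do not certify performance on human recordings.

Because synthetic trials are generated *from* the temporal model, the data
matrix has the same low rank in both arrangements, and the real-data
finding that spatial extractions need several more components than temporal
ones is not reproduced at desk scale: the count-difference statistic is
computed by the same operation, but on synthetic cohorts it hovers near
zero. The published model orders are therefore used as inputs when
exercising the compactness arithmetic.

## Problem sizes and numerical choices

Library defaults are the study-scale settings (n up to 30, 5 folds, 50 NMF
restarts, 3 000 iterations, 50 k-means restarts, 10 matching repeats,
α = 0.05). Tests and the acceptance script run scaled-down instances chosen
as the smallest sizes at which each property is identifiable: cohorts of
1–12 participants, 3–4 planted synergies, order scans to n ≈ 6–8, 2–5 NMF
restarts with 300–2 000 iterations, 500 null / 200 planted-effect
mixed-model replicates at 10 participants x 6 trials. These sizes are the
package's own validation design.

Other numerical choices: NMF multiplicative updates are guarded with 1e-12
denominators; all-zero factor columns keep scale 1 during unit-max
renormalization; NNLS (scipy) fits trial-dependent factors per column; R²
of a single-column fit is reported as NaN (its row-mean SST is zero);
k-means singleton clusters are assigned correlation 1 (a centroid equals
its only member); FWHM tie-breaks take the earliest peak sample.

## Known limitations

* The event detector and ECG remover are operationalizations of procedures
  whose cited details are not in the source text; both are parameterized and
  documented rather than claimed identical.
* The "multivariate" mixed model is the stacked-response reading with one
  residual variance; muscle-heteroscedastic extensions are out of scope.
* Model selection consumes the across-fold mean R² curve; per-fold knee
  selection would give a distribution of orders instead.
* The spatial-vs-temporal compactness asymmetry of real EMG cannot emerge
  from a generator that is itself a temporal-synergy model (above).
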