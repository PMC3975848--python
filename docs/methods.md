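# Methods

`vmil` implements a complete cross-subject EEG decoding analysis for
visuomotor integration and learning (VMIL): predicting a subject's
trial-to-trial motor performance in a 3D reaching task from the EEG
preceding each movement, together with the synthetic cohorts needed to
exercise every stage against a known ground truth. This note documents the
model, the generative assumptions, the numerical choices, and what the
package's tests do and do not establish about real data.

## The behavioural measure

Performance on each trial is the **normalized time-to-target (TTT)**: the
time from the go cue to target contact divided by the start-to-target
distance, in s/m. Trials that hit the movement time limit take the full
limit duration and carry a timeout flag. Over a session, practice drives a
slow decline of TTT toward an asymptote; the analysis asks whether the
*slow* component of that decline is visible in pre-trial brain activity.

## Synthetic cohorts

No public recordings exist for this paradigm, so the package generates
cohorts whose structure matches the study design: 6 subjects, 200 trials in
4 blocks of 50, trial phases baseline (5 s), planning (2.5–4 s, uniform),
go (≤ 10 s) and return, EEG sampled at 250 Hz over 32 channels (both
configurable; the generator accepts the 1 kHz / 120-channel geometry of a
full-scale lab recording, the defaults keep simulations desk-scale).

The generative model:

- **Learning curve.** A latent state decays as `exp(-t / tau)` over the
  0-based trial index (1 on the first trial, → 0). Expected TTT is the
  affine map of the latent onto [asymptote, initial]; observed TTT adds
  i.i.d. Gaussian noise. Defaults: initial 40 s/m, asymptote 10 s/m,
  tau 50 trials, noise sd 3 s/m — a fast early improvement that flattens
  within the session, with ~18% trial-to-trial variability. Per-subject
  parameters get lognormal jitter (20% relative sd) so subjects share a
  curve family but not a curve. A single-process exponential is the
  conventional minimal learning model and is exactly recoverable, which is
  what a ground-truth target needs.
- **Sources.** Each cortical source is narrow-band Gaussian noise on a
  `1/f` background, with one spectral line per source: informative sources
  on dedicated slots inside their coupled band, the rest spread evenly
  over 4.5–29.5 Hz (theta through beta) with a 1.5 Hz guard zone around
  every informative line. Distinct lines are a modelling *choice with a
  purpose*: second-order blind separation can only distinguish sources
  with distinct autocorrelations, so near-coincident lines would make the
  mixture unidentifiable in principle, not just hard to estimate.
- **Coupling.** Designated sources scale their narrow-band amplitude per
  trial by `exp(strength * (latent - 0.5))`. The default couples two
  sources' alpha/mu (8–14 Hz) rhythm at strength −0.15: band power *rises*
  as learning proceeds, i.e. enhanced alpha/mu goes with better
  performance. The magnitude is a calibrated effect size (see *Calibration*
  below).
- **Mixing.** Sources project to channels through a random unit-column
  mixing matrix shared across the cohort up to 5% relative Gaussian jitter
  per subject (anatomical variability that pooled decomposition must
  tolerate), plus i.i.d. sensor noise. One optional artifact source
  (broadband 40–120 Hz, single-channel-dominated topography, on by
  default) exercises automated component rejection.

All randomness derives from one seed through per-(subject, purpose)
streams, so cohorts are bit-reproducible.

What the generator deliberately does **not** emulate: volume conduction
from a head model, non-stationary artifacts (blinks, EMG bursts, electrode
drift), within-trial dynamics of band power, and any nonlinearity between
cortical state and behaviour. Passing tests therefore show the *pipeline*
is sound — separation recovers planted sources, the decoder finds planted
couplings at realistic effect sizes, inference behaves as analysed — not
that real EEG satisfies the generative assumptions.

## Pipeline

1. **Referencing/filtering.** Common average reference per recording, then
   two zero-phase third-order Butterworth high-pass versions: 3 Hz for
   fitting the source separation (slow potentials otherwise dominate the
   covariance), 0.1 Hz for feature extraction (the delta feature band
   starts at 0.1 Hz and would be empty in the 3 Hz data). Zero-phase
   filtering doubles the effective order but leaves epoch timing intact.
2. **Pooling/PCA.** Subjects are concatenated in time; the pooled channel
   covariance is eigendecomposed and the data reduced to the top
   components (default: the generative source count for synthetic data; 64
   is the conventional choice for a 120-channel recording). Scores are
   whitened because joint diagonalization assumes unit lag-0 covariance.
3. **SOBI.** Time-lagged covariances (lags 1–50 samples, i.e. 4–200 ms at
   250 Hz) are symmetrized and jointly diagonalized by Jacobi sweeps with
   the closed-form Givens angle for sets of real symmetric matrices
   (rotation tolerance 1e-8, ≤ 200 sweeps; the off-diagonal criterion is
   non-increasing by construction). Components are ordered by total lagged
   autocovariance energy and sign-fixed on the largest topography weight —
   conventions, since ICA is only defined up to permutation and sign.
4. **Component rejection.** An automated stand-in for manual inspection: a
   component is dropped if >50% of its power lies above 40 Hz, its 3–40 Hz
   log-log spectral slope is outside (−8, 1) (the permissive upper bound
   keeps band-peaked rhythms like beta whose net slope is near zero), or
   one channel carries >80% of its squared topography weight. An empty
   kept-set is an error: the pipeline cannot proceed without sources.
5. **Features.** Per trial and kept component, log band power (Hann window,
   single FFT over the epoch, power summed over bins in the band, natural
   log with a 1e-12 floor) in delta 0.1–4, theta 4–7, alpha/mu 8–14, beta
   20–30 and gamma 55–85 Hz. Epochs: 5 s of baseline; the first 2.5 s of
   planning (its guaranteed minimum duration, keeping epochs equal-length).
   Feature series are then low-pass filtered **across trials** at
   c = 0.1 rad/trial — the analysis targets slow drifts, and the TTT
   periodogram shows its informative energy lives below that cut-off.
   Columns are ordered component-major, band-minor, so tables from
   different subjects align for cross-subject training.
6. **Decoding.** A bagged ensemble of CART trees with random per-split
   feature subsets (500 trees, candidate features ⌈p/3⌉, minimum leaf 5,
   bootstrap on), trained to predict the trial-domain low-passed,
   per-subject standardized TTT under leave-one-subject-out
   cross-validation. Within-subject cross-validation would be invalid
   here: trials are strongly autocorrelated through the learning curve, so
   train/test splits within a subject share information; subjects are the
   exchangeable unit. Standardizing per subject removes between-subject
   TTT scale, which a cross-subject model cannot and should not predict.

### Trial-domain filter details

The trial-domain low-pass treats one trial as one sample: cut-off c in
radians per trial (c = 0.1 ≈ 0.016 cycles/trial, a ~63-trial period).
Realized as a third-order Butterworth applied forward–backward with
reflect padding spanning about one cut-off period (`min(n-1, max(9,
ceil(2*pi/c)))` samples): the filter's transient decays over ~1/c trials,
and a materially shorter pad leaks edge transients into 200-trial series.
A constant series passes through unchanged; series shorter than 20 trials
are rejected.

## Prediction quality: R²_mod

Because inputs are band-limited in the trial domain, the model cannot
express fast TTT fluctuations, and plain R² understates prediction
quality. The package scores predictions with

    R²_mod(x, y) = R²(x, y) / R²(x, LP(x, c)),

where x is the held-out subject's standardized TTT, y the prediction, and
LP(x, c) the trial-domain low-pass of x. The denominator is the best R²
achievable by any model confined below c, so R²_mod ranges over (−∞, 1]:
1 means all explainable slow variance explained, 0 matches the mean
predictor, negative values mean variance was added. The statistic is
undefined (and raised as an error) when the denominator is non-positive,
i.e. when x has no explainable slow variance.

## Group inference and its limits

Group-level significance uses a permutation test: each subject's observed
series is independently trial-shuffled, the per-subject R²_mod recomputed
against the fixed predictions, aggregated (mean by default; the median is
also reported), 10,000 times; the p-value uses the add-one estimator so it
is never zero. Two conventions are implemented for the denominator under
permutation:

- **fixed (default):** each subject's observed denominator is reused, so a
  draw is a positively-scaled permutation statistic of the numerator;
- **recompute:** the denominator is recomputed on the shuffled series.
  Shuffling destroys slow structure, so the recomputed denominator
  collapses toward zero and draws are dominated by it rather than by the
  predictions; with this convention the observed statistic beats
  essentially every draw regardless of coupling. Subjects whose recomputed
  denominator is non-positive contribute 0 to such a draw (no explainable
  slow variance ⇒ no credit).

**Known limitation — the test is anti-conservative under this design.**
Independent trial permutation tests the hypothesis that the observed
series is *exchangeable across trials*. A learning curve is not: it is
dominated by a slow trend even when the EEG carries no information. With
band-limited predictions, the observed R² is a correlation between two
smooth series (~n·c/π effective degrees of freedom, ≈ 6 at the defaults),
while permutation draws correlate a shuffled — white — series with a
smooth one (~n effective d.o.f.). The observed statistic is therefore
stochastically larger in magnitude than its draws even under independence.
The package's calibration harness (`vmil.calibration`) measures this:
coupling-free cohorts yield bimodal p-values (near 1/(n_perm+1) or near 1)
and a false-positive rate far above the nominal level — about 50% at
α = 0.05 with the fixed denominator, ~100% with the recomputed one — while
a diagnostic variant with unfiltered (white) null predictions is close to
calibrated. A small p-value from this test is thus evidence against
trial-exchangeability of the observed series given the predictions, not
specifically evidence that the EEG informs performance; structured nulls
(e.g. block or cyclic shifts) would be needed for the latter. The harness
runs at the feature level (per-trial band-power estimation noise is
i.i.d. across trials once the coupling is off, and the omitted EEG stages
are invertible linear maps), which is what makes 100-replicate calibration
studies affordable.

## Interpretation

- **Variable importance** (out-of-bag permutation importance): per tree,
  the mean squared error on its out-of-bag rows is compared with the error
  after permuting one variable among those rows (10 repeats, averaged);
  the averaged increase, in target-variance units, is the importance.
  Correlated informative variables dilute each other's importance, so
  per-fold ranks and a top-k consistency score across folds are reported
  alongside raw values.
- **Feature influence**: a variable is fixed to a value v̂ in every
  training row, the ensemble predicts, and the mean output is recorded —
  swept over 50 evenly spaced values between the variable's training
  minimum and maximum (outside that range trees saturate, so wider grids
  add nothing). This partial-dependence-style curve shows the direction
  and shape of the variable's marginal effect; on default synthetic
  cohorts the injected alpha/mu variables produce monotonically decreasing
  curves — higher alpha/mu power, lower predicted TTT.

## Calibration of the default effect size

The coupling strength is the one generator parameter with no external
anchor, so it is calibrated once against the scale of results the analysis
is designed for: at strength −0.15 the full planning-phase pipeline yields
per-subject R²_mod of roughly 0.0–0.5 (group median ≈ 0.2) — the regime
reported for human cross-subject decoding of this kind — while the group
permutation p stays below 0.001 and the injected variables dominate both
interpretation views. At this strength the *single-trial* coupling is
deliberately weak: per-trial log-band-power estimation noise is ≈ 0.45
log-units (a chi-square with ~2·T·B degrees of freedom for epoch length T
and signal bandwidth B), against a full-session log-power swing of 0.3, so
single-trial correlations with the latent state are small (|ρ| ≈ 0.1) and
the effect becomes decodable only through the trial-domain filter. Strong
coupling (−0.8) makes the per-trial association itself large
(|Spearman ρ| > 0.5) and pushes R²_mod toward 0.85; the tests probe both
regimes.

## Numerical and degenerate-input conventions

- Power floor 1e-12 µV² before the log (a zero epoch maps to log(1e-12)).
- R² requires a non-constant observed series; z-scoring rejects constant
  input; the R²_mod denominator must be positive.
- Joint diagonalization warns (does not fail) if it exhausts its sweep
  budget, reporting the final off-diagonal criterion; a rotation angle
  below 1e-8 counts as converged.
- Forest determinism: every fold/stage seed derives from the single global
  seed via named seed-sequence streams; identical configs reproduce
  reports bit-for-bit (timestamps aside).
- EEG arrays are carried as float32 (a 6-subject default cohort is ~0.5 GB
  of signal); covariances and everything downstream of epoching are
  float64.

## Problem sizes used by the shipped checks

The default study conditions (6 subjects × 200 trials at 250 Hz / 32
channels) run end-to-end in a few minutes on one CPU; the test suite runs
that configuration once and reuses it. Unit tests use a 3-subject,
40-trial, 12-channel cohort with strong coupling so every effect is
detectable in seconds. Source-recovery checks use a 10-source, 200-trial
single-subject mixture. Calibration studies use 100 feature-level
replicates with a thinned forest (60 trees, 20 features), which preserves
the statistic's null behaviour.
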