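# Methods

This note documents the models, numerical conventions, and design choices
behind `imagcond`, and what the synthetic cohort does and does not emulate.

## Experimental design generation

Each phase has six habituation runs (8 trials: 2 per modality × CS cell,
fully randomized, never reinforced) and six acquisition runs (12 trials:
2 reinforced CS+ and 2 non-reinforced CS+ of the conditioned modality,
4 conditioned-modality CS−, 2 CS+ and 2 CS− of the other modality). The
conditioned modality is *imagine* in the imagery acquisition phase and
*view* in the visual acquisition phase, giving a 50% reinforcement rate for
the conditioned CS+ in both phases.

Placement constraints, enforced by construction and by an independent
validator:

- every acquisition run begins and ends with a conditioned-modality CS−
  trial (both phases — the visual phase mirrors the imagery phase's rule);
- run 1 places its first reinforced CS+ at trial 2 and its second uniformly
  in the second half; every later run places one reinforced CS+ per half.
  "Halves" of a 12-trial run are positions 2–6 and 7–11, excluding the fixed
  CS− endpoints. The per-half rule is applied to *all* five runs after run 1;
- remaining trials are uniformly shuffled, seeded per
  (seed, participant, phase), so schedules are deterministic and distinct
  across participants.

Analysis-trial selection drops reinforced trials (shock confound) and, for
the conditioned modality, the first and last CS− trial of each run, leaving
12 CS+ and 12 CS− analysis trials per modality per phase — balanced classes
for both the SCR aggregation and the classifiers.

**Timing.** The published trial structure fixes a 4 s CS epoch preceded by a
2 s auditory cue, with the shock co-terminating with the CS. Inter-trial
gaps are drawn uniform(1, 2) and rescaled so each run fills its duration
(habituation 146 s, acquisition 218 s; 73/109 volumes at TR = 2 s). The true
ITI distribution of the study is not reported; any positive gap distribution
longer than the response windows would serve. The `onset` field is the CS
onset; the US is stored as a flag (its 2 ms delivery is metadata, not an
epoch).

## SCR scoring

Amplitude = max of the trace over [onset+1 s, onset+6 s] minus the mean over
[onset, onset+1 s) (half-open to avoid double-counting the boundary sample).
Deflections ≤ 0.02 µS score exactly zero. Scores are square-root transformed
per trial *before* averaging, and zero trials are retained in condition
means (magnitude-style averaging), matching the convention of scoring
sub-threshold trials as zero rather than discarding them. The scorer is
sampling-rate agnostic (tested at 50–1000 Hz) and invariant to constant
offsets. A participant whose scored amplitude is zero on every reinforced
trial is flagged as a non-responder. No minimum-rise-time or latency
criteria beyond the window are imposed.

## Trial-wise GLM

The first level is a least-squares-all beta series: one regressor per
analysis trial (4 s boxcar convolved with the HRF, 20× oversampling,
sampled at volume times), plus collapsed nuisance regressors for reinforced
trials and the boundary CS− trials, an intercept, and optional Legendre
drift terms. The HRF is the common double-gamma parameterization — gamma
densities with modes at 6 s and 16 s, undershoot ratio 1/6, 32 s support,
scaled to unit peak; the family is standard and the specific parameters are
the field's defaults. Estimation is OLS; prewhitening, smoothing, and
registration are deliberately out of scope because the downstream inference
(decoding with resampling nulls) does not depend on them at this scale.
"Normalized parameter estimates" is implemented as z-scoring of trial betas
per voxel within run; the precise normalization used in the original
pipeline is not stated, and z-scoring is the conventional reading.

## MVPA cross-classification

The classifier is a linear SVM with fixed C = 1 (no hyperparameter search
is described for the original analysis). Feature selection — either the full
ROI or the k = 300 voxels with the largest mean |beta| — is computed on
training data only, with ties broken toward the lower voxel index, to
exclude leakage. Internally the SVM runs on a precomputed linear Gram
matrix, and the permutation loop calls the underlying libsvm fit/predict
routines directly; this is the identical estimator to
`SVC(kernel="linear")` (exact-agreement test included) and makes
10 000-iteration nulls tractable on one core.

Two-level inference: per participant, training labels are shuffled
uniformly (independent draws, not exhaustive enumeration — the orbit of
label orderings is astronomically larger than the iteration count), the
classifier retrained, and the held-out accuracy recorded. The group null
draws, per iteration, one permuted accuracy per participant with
replacement and records the across-participant mean. The observed group
mean is compared one-sided (above chance) with the add-one estimator
p = (1 + #{null ≥ obs}) / (1 + n_boot), which cannot return zero. The
procedure is calibrated: on signal-free cohorts the rejection rate at
α = .05 stays within sampling error of nominal (acceptance suite), and the
group-null mean sits at 0.50 for balanced designs.

## Statistics layer

- **Paired t / Cohen's d.** d = t/√n for the paired design. A zero-variance
  difference with nonzero mean raises a distinct `InfiniteTError`.
- **JZS Bayes factor.** BF₁₀ = m₁/m₀ where m₁ integrates the noncentral-t
  likelihood over a Cauchy(0, r) prior on the standardized effect
  (default r = 0.707) via adaptive quadrature after the substitution
  δ = r·tan θ, which maps the heavy tails onto (−π/2, π/2); m₀ is the
  central-t density. Convergence is guarded at 1e-4 relative error
  (achieved ~1e-6). The test suite cross-checks against an independent
  brute-force oracle using the inverse-gamma mixture representation
  (elementary functions, dense trapezoid over the auxiliary variance) and
  against `pingouin.bayesfactor_ttest`. A sensitivity grid over
  r ∈ {0.5, 0.707, 1.0, 1.41} is exposed.
- **RM-ANOVA.** Classical fully-within decomposition on the balanced
  subject × cell array by inclusion–exclusion over marginal means; each
  effect is tested against its effect × subject stratum
  (F(1, n−1) throughout for 2×2×2). η² is *classical*
  (SS_effect / SS_total including the subject stratum), not partial: the
  small published η² values (e.g. 0.010 alongside F = 39.90) are only
  consistent with the classical definition, since partial η² would be
  F/(F + df_error) ≈ 0.6. F and p are verified against
  `statsmodels.AnovaRM`, and the single-factor case reproduces F = t².

## Synthetic cohort

Defaults describe the emulated study: 27 participants, a 248-voxel ROI
(the anterior-insula cluster size that anchors the ROI analyses), 50%
reinforcement via the design module. Where the study reports no
quantitative generative values, defaults were chosen once as realistic for
the modality and are not tuned: SCR response means 0.4/0.15 µS
(CS+/CS−) with a 0.6 µS unconditioned increment on shock trials, 25%
non-response trials, smooth trace noise of 0.01 µS on a 2 µS tonic level
with a 0.002 µS/s drift; pattern separation 0.8 noise-sd units with 60%
of discriminative energy shared between modalities; AR(1) BOLD noise with
coefficient 0.3; a +1.8 latent-scale CS+ shift on ratings of which half
generalizes to the unconditioned modality.

Mechanics worth knowing:

- **Determinism.** Every artifact is a pure function of
  (config, participant, phase, run); seeds derive from a seed-sequence key,
  so cohorts are reproducible element-wise, not just in aggregate.
- **SCR kernel.** Sigmoid rise × exponential decay (midpoint 2.2 s, scale
  0.3 s, decay 4 s), unit peak at ≈2.95 s post-onset — inside the 1–6 s
  scoring window, with negligible mass in the baseline second. Simulation
  default is 100 Hz rather than the hardware's 2000 Hz; the scorer is
  rate-agnostic, so nothing downstream depends on this.
- **Patterns.** Per participant, an orthonormal triple (shared, view-
  specific, imagine-specific) is drawn once and reused across phases, so
  cross-phase decoding meaningfully probes a persistent representation;
  `shared_fraction` is exactly the squared cosine between the two modality
  directions. Noise is isotropic — correlated voxel noise is left as a
  config extension.
- **Heterogeneity.** Participant random effects (normal hyperpriors on the
  pattern separation, SCR amplitude, and rating intercept) keep group-level
  inference non-degenerate.
- **Ratings.** Latent normal rounded and clipped to 1..7. Clipping makes
  the paired t on null data very slightly conservative/anticonservative
  depending on the baseline; the calibration test allows 2–9% rejection at
  nominal 5%.

What the generator does **not** emulate: tonic electrodermal drift beyond a
linear term, motion or physiological artifacts, draining-vein or
spatial-autocorrelation structure in BOLD, habituation of responses across
runs, and any coupling between the SCR, rating, and pattern effect sizes
within participant. Passing tests therefore certify the *pipeline* —
bookkeeping, estimators, resampling inference, calibration — under the
assumed generative structure, not the biological claims of any real
dataset.

## Problem sizes

Simulation-based checks run at desk scale, chosen as the smallest sizes at
which the targeted property is identifiable: decoding calibration uses
8-participant cohorts with 60-voxel ROIs, 500 permutations × 500 bootstrap
iterations × 200 replicate experiments; the power/transfer checks use a
separation of 6 noise-sd units ("large": optimal accuracy Φ(3) ≈ 0.999)
with 100 replicates at 300/300 resampling; GLM recovery sweeps 50 runs with
common-random-number noise scaling so RMSE monotonicity is exact rather
than statistical. The study-scale 10 000-iteration nulls are a parameter
change (`n_perm`, `n_boot`), not a code path change.

## Known limitations

- The permutation scheme shuffles training labels only; schemes that also
  respect run structure (stratified shuffles) are not implemented.
- `select_analysis_trials` assumes the generated design's composition; it
  validates but does not repair malformed schedules.
- The Bayes factor is the two-sided default; one-sided (directional)
  variants are not exposed.
- NIfTI ROI masks are flattened to linear voxel indices; no geometric
  operations (erosion/dilation) are provided.
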