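# Methods

## Analysis model

The unit of all inference is the subject × condition mean LPP amplitude:
per trial, the mean voltage over the 10 centro-parietal ROI sensors and
over the half-open 400–800 ms window; per subject × valence × instruction
cell, the mean over surviving trials. Preprocessing before scoring is
deliberately minimal and explicit: baseline correction over a pre-stimulus
window (default [−0.1, 0] s), average referencing, and rejection of trials
containing any sample with |voltage| above a threshold (default 100 µV).
The published analyses this package operationalizes describe their
preprocessing chain only in supplementary material; the defaults here are
therefore documented stand-ins, overridable in `AnalysisConfig`, and each
run's report flags that stand-ins are in effect. Channel interpolation,
filtering, and ocular correction are out of scope.

Windows are half-open `[start, end)` everywhere so scores are invariant to
sampling rate and the 0.8 s edge is never double-counted; at 250 Hz with an
epoch starting at −0.1 s the LPP window covers exactly 100 samples.

Winsorization is applied at the subject-mean level, within each valence ×
instruction condition across subjects, at the 1st/99th percentiles
(linear-interpolation percentile rule). Per-condition scoping prevents
genuine condition effects from being clipped as outliers. Both the level
(`subject`/`trial`) and the scope (`condition`/`pooled`) are configurable
because the original description ("LPP values were winsorized") fixes
neither; the number of replaced values is logged.

## Contrasts and the decision rule

Per subject, with instruction means pooled over the two emotional valences
(`scope="pooled"`; single-valence scopes are also available):

- reappraisal score `E − S`, weights (0, 1, −1);
- cognitive-load score `2V − E − S`, weights (2, −1, −1), raw weights kept
  so the mean difference is in microvolts on the published scale.

The weight vectors are orthogonal; under exchangeable condition noise the
two scores are uncorrelated, so each contrast's one-sample *t* and JZS BF01
carry separable evidence. The three-way decision is an interpretive layer
formalizing the verbal argument, with thresholds taken from the
conventional evidence categories (configurable):

- `cognitive_load`: load BF01 < 1/3 with positive mean load AND
  reappraisal BF01 > 1;
- `reappraisal`: reappraisal BF01 < 1/3 with positive mean;
- `null`: both BF01 > 3;
- `indeterminate`: otherwise.

With n = 107 subjects and a true load effect of dz = 0.33, the BF01 = 1/3
boundary sits at t = 2.66, so the decision rule's power is ≈ 0.78 for the
load regime and ≈ 0.76 for the null regime (each null contrast clears
BF01 > 3 with probability 0.87, and both must) — recovery rates in the
high 70s–low 80s per cent are the expected behaviour of the rule at this
effect size, not an implementation artefact.

## Bayes factors

Both Bayes factors are computed by adaptive quadrature of one-dimensional
marginal-likelihood integrals, with the integrand ratio evaluated in log
space; BF01 (null over alternative) is the reporting convention
throughout. Integration uses the change of variables g = u/(1−u) for the
t-test (absolute tolerance 1e−12, relative 1e−10, failure raises rather
than falling back) and a breakpoint at ρ = r for the correlation, whose
integrand sharpens towards |r| → 1. The t-test BF uses the Cauchy
(scale √2/2) prior on standardized effect size expressed as the standard
inverse-gamma mixture over the variance ratio; the correlation BF uses the
symmetric stretched-beta prior of width κ = √2/2 with the exact sampling
density of r (Gauss hypergeometric form). The stretched-beta formulation
was selected because it reproduces the published reference values computed
with the same prior width (including BF01 = 6.75 at r = 0, n = 107
exactly); the alternative route via the t-statistic sampling relation
misses them by 35–50% and was rejected. Tests pin both integrals to
brute-force Riemann oracles (10⁶ log-grid nodes) at 4 significant figures
and to an independent library implementation.

Evidence labels use the 1/10, 1/3, 3, 10 thresholds with boundary values
assigned to the weaker category.

## Frequentist inference

The repeated-measures ANOVA is implemented from the sums-of-squares
decomposition (orthonormal-contrast form): for each effect, per-subject
effect scores Z = YM give SS_eff = n‖Z̄‖² and error SS = Σ‖Z_s − Z̄‖²;
Box's ε̂ comes from the covariance of Z (clamped to [1/df, 1], fixed at 1
for single-df effects) and GG-corrected p-values use ε-scaled degrees of
freedom. Generalized η² treats all within-subject factors as manipulated:
SS_eff / (SS_eff + SS_subjects + all error SS). The implementation is
cross-checked against a longhand loop-written oracle on a fixed 6-subject
table and against pingouin to machine precision; for k = 2 it reduces
exactly to the paired t (F = t², ε = 1).

Effect sizes: dz = mean(d)/sd(d) = t/√n, with the 95% CI by the normal
approximation dz ± 1.96·√(1/n + dz²/2n) — chosen over noncentral-t
inversion because it reproduces published intervals at n = 107 (e.g.
dz = 0.41 → [0.21, 0.61]). Pairwise tests are reported uncorrected, as is
standard for planned comparisons in this design.

## Robustness

Sequential Bayes factors recompute each contrast's BF01 on the first n
subjects of each of `seq_orderings` random permutations (default 500),
n from 20 to N in steps of 1; the central trace is the median and the band
the 5th–95th percentiles across orderings (one reading of a "90% interval
across orderings"; the alternative mean ± z·SD is not used). With a single
ordering the identity permutation is used, making the full-grid endpoint
exactly the full-sample BF01.

The bootstrap resamples *subjects* (never trials) with replacement,
default 10 000 resamples, reporting the percentile 95% CI of dz and the
fraction of resamples above zero; a zero-variance resample receives
sign(mean)·10⁶ and is counted. Coverage of the percentile CI at dz = 0.3,
n = 107 is verified at 93–97% over 500 replicates.

## Decoding

The decoding unit is the per-subject condition-mean sensor pattern (one
pattern per class per subject), because subject-level inference is the
target and per-trial counts are not part of the public record.
Cross-validation folds split subjects; no subject contributes to both
training and test. The classifier is a regularized linear discriminant
with a diagonal pooled covariance estimate, w = Δμ/(v + λ),
λ = 0.1·mean(v) — a documented stand-in (the reference pipeline's
classifier is supplementary-only); the permutation null makes the choice
calibration-safe. The null relabels the two conditions within subject
(a sign flip of the within-subject pattern difference) and retrains
end-to-end; the significance envelope is the pointwise 97.5th percentile
over (default) 1000 permutations, with no cluster correction. Full-epoch
features are sensor × 20 ms-binned amplitudes over 0–1 s; accuracy gets a
binomial normal-approximation CI over held-out predictions, AUC comes from
the held-out decision scores, and the permutation p is
(1 + #{perm ≥ observed}) / (1 + n_perm).

## Synthetic-study generator

The generator emulates the study conditions: 107 subjects, 129 channels at
250 Hz, epochs −0.1 to 1.0 s, seven design cells (neutral appears under
View only), all second-presentation trials with 1–7 ratings.
`trials_per_cell = 24` is a documented stand-in — the real per-cell trial
count is not public.

Each trial is per-channel 1/f (pink) noise, synthesized by spectral
shaping of white Gaussian coefficients (zero DC, amplitude set by
`pink_noise_scale`, default 2 µV per-sample SD), plus a late-positivity
template: a Hann bump spanning 0.3–0.9 s, spatial weight 1 on the ROI
channels and a fixed smooth negative falloff elsewhere (zero-sum across
channels, so the template is invariant under average referencing), scaled
so one amplitude unit equals 1 µV of ROI-window mean. The neutral/View
baseline amplitude is 5 µV; a per-subject intercept (SD 2 µV) cancels in
all contrasts.

Effect calibration works on the measured score's variance model: subject ×
condition means have variance σ_m² = subject_sd² + trial_noise_sd²/m, so a
two-cell difference with target dz needs amplitude dz·√(2σ_m²)
(`calibrate_amplitude`). The configured `trial_noise_sd` (default 5 µV) is
the *total* per-trial SD of the measured score: the pink-noise
contribution to the window-minus-baseline ROI mean is computed exactly
from the synthesis filter (the noise is a linear map of Gaussian
coefficients) and subtracted in quadrature from the amplitude jitter;
a configuration in which pink noise alone exceeds the trial budget raises
a calibration error.

`instruction_dz` (default 0.33) targets the valence-pooled per-subject
contrast score — the adjudication unit. Pooling halves the cell variance,
so the pooled load score has variance 3σ_m² and the pooled reappraisal
score σ_m². This single choice reproduces the published effect scale
three ways: pooled load mean ≈ 0.8 µV, pooled load dz = 0.33, and implied
per-valence pairwise effects ≈ 0.23. The emotion effect
(`emotion_dz` = 0.45) is calibrated per-cell (emotional vs neutral under
View) and applied equally to pleasant and unpleasant; the load regime
lowers both instructed cells equally, the reappraisal regime shifts
Enhance up and Suppress down symmetrically, and the null regime applies no
neural instruction effect.

Ratings are generated on a latent continuous scale (valence bases
3.6/4.6/5.1 for neutral/pleasant/unpleasant; subject-condition SD 0.5,
trial SD 1.2) with instruction shifts calibrated the same way
(`rating_enhance_dz` = 0.62, `rating_suppress_dz` = 0.42, per-valence),
then rounded and clipped to 1–7. Discretisation attenuates realized effect
sizes by a few per cent at most, which the Monte-Carlo tolerances absorb.
Rating effects are applied in every regime — the behavioural/neural
dissociation is the generator's point.

Randomness: one master `SeedSequence` per study, spawning one substream
per subject, so any subject can be regenerated independently and all
outputs are bit-reproducible from `rng_seed`.

`simulate_condition_means` / `simulate_rating_means` draw the subject ×
condition mean tables directly from the same mean model. Because the
EEG-to-score map is linear, the induced score distribution is exactly the
mean model with variance σ_m²; the fast path is what large replicate
studies (type-I calibration at 1000 replicates, 100-seed recovery runs)
use, while full EEG synthesis is exercised end-to-end at the study scale
in single-run tests. Replicate counts and scales used by the test suite
(100 recovery seeds per regime, 1000 type-I replicates, one full-scale
EEG study shared between the end-to-end and decoding checks with 200
permutations) are the package's own choices balancing Monte-Carlo error
against runtime.

### What the generator does not emulate

No head-model forward physics, no spatial channel correlation beyond the
template, no eye-blink/EMG artifacts, no first-presentation trials, no
arousal substructure, and Gaussian subject effects throughout. Passing
tests therefore demonstrate that the *statistical machinery* is correct
and calibrated under the stated variance model — not that the pipeline is
robust to real-EEG pathologies (drifts, correlated noise, heavy-tailed
subjects).

## Known limitations

- The decision rule is a formalization of a verbal argument; its
  thresholds (3, 1/3) are conventional, and at dz ≈ 0.33 its single-study
  power is ≈ 0.75–0.80 (see above). It is exposed as configurable rather
  than hidden.
- Correlation BF01 values are computed from the correlation actually
  observed; published values computed on unrounded statistics can differ
  in the second decimal from values recomputed at 2-d.p. rounded inputs.
- The artifact-rejection, baseline, and classifier choices are stand-ins
  for supplementary-only specifications and are flagged in every report.
- `winsorize_table` requires ≥ 2 distinct values per condition; degenerate
  conditions pass through unchanged (logged).
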